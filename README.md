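# npdkit

Analysis toolkit for **nasal potential difference (NPD)** measurements, the
only in vivo assay of CFTR- and ENaC-mediated ion transport used in cystic
fibrosis (CF) diagnostics. It is written for CF-center analysts and
methods researchers who need to go from raw voltage tracings to diagnostic
calls and repeatability statistics with a fully scripted, auditable pipeline.

## What it computes

An NPD exam perfuses the nasal mucosa with a fixed solution sequence —
Ringer's, amiloride, chloride-free + amiloride, then + isoproterenol — each
for at least 3 min, ending on a stable plateau (PD change < 1 mV for ≥ 30 s).
From the end-of-phase plateaus the pipeline extracts, in mV:

- **PDmax** — maximal basal PD (Ringer plateau; hyperpolarized in CF),
- **Δamil** — amiloride response, plateau(amiloride) − plateau(Ringer)
  (ENaC depolarization; larger in CF),
- **TCR** — total chloride response, plateau(isoproterenol) −
  plateau(amiloride) (CFTR-dependent hyperpolarization; near zero in CF),

and from those the two published composite diagnostic scores

```
WI = exp(TCR / Δamil)          CF predicted when WI > 0.7
SS = −0.11·TCR − 0.05·Δamil    CF predicted when SS ≤ 0.27
```

plus the residual-CFTR-function category on TCR alone (normal < −12 mV,
intermediate −12 to −7.7 mV, no function > −7.7 mV). Cohort-level analyses
follow the field's reporting conventions: per-group mean (SD) with t-based
95% CI and median (range), one-way ANOVA with Scheffé post-hoc contrasts,
Levene and Kruskal–Wallis checks, and Bland–Altman agreement
(mean difference ± 1.96 SD limits) for repeated exams. A calibrated
simulator generates cohorts and full synthetic tracings with known ground
truth for validation.

## Worked example

```python
import npdkit as nk

# a synthetic tracing at the typical CF parameter values
t = nk.simulate_tracing((-31.7, 15.0, -1.5), seed=7, subject_id="CF001")
p = nk.extract_parameters(t)
print(f"PDmax {p.pdmax:.1f} mV, Δamil {p.damil:.1f} mV, TCR {p.tcr:.1f} mV, "
      f"QC pass: {p.qc_pass}")
s = nk.score_parameters(p)
print(f"WI {s.wi:.2f} ({s.wi_class}), SS {s.ss:.2f} ({s.ss_class}), "
      f"TCR category: {s.tcr_category}")

# repeatability of a simulated two-exam cohort (11 CF / 19 non-CF / 48 healthy)
sim = nk.simulate_cohort(repeats=2, seed=1)
print(nk.BlandAltman.from_cohort(sim.cohort, "pdmax_mv").fit().summary())
```

prints

```
PDmax -31.8 mV, Δamil 15.1 mV, TCR -1.5 mV, QC pass: True
WI 0.91 (CF), SS -0.59 (CF), TCR category: no_function
Bland-Altman agreement: pdmax_mv (first − second), n = 78
  mean difference -0.87 (SD 8.57), 95% CI (-2.81 to 1.06)
  limits of agreement (-17.68 to 15.93)
  pairs outside limits: 3 (healthy005, non_CF006, non_CF007)
```

The extracted parameters recover the simulated truth to within the plateau
noise; WI 0.91 > 0.7 and SS −0.59 ≤ 0.27 both call CF, and the near-zero TCR
places the subject in the "no function" CFTR category. The Bland–Altman
block quantifies between-exam agreement: bias near zero and ~95% of paired
differences inside the limits.

The same pipeline is available from the shell via the `npd` console script
(`npd simulate | extract | score | groupstats | repeatability`); each
subcommand reads/writes the plain CSV formats documented in `npdkit.io`.

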