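# Methods

## The measurement and its parameters

Nasal potential difference (NPD) measures the transepithelial voltage of the
nasal respiratory mucosa while solutions are perfused in a fixed sequence:
Ringer's (basal), 100 µM amiloride (ENaC block), chloride-free + amiloride
(chloride-gradient driven efflux), and + 10 µM isoproterenol
(cAMP-stimulated, CFTR-dependent efflux). Each solution runs for at least
3 min and must end on a stable plateau before the next phase starts. The
analysis parameters are differences of end-of-phase plateau values:
PDmax (Ringer plateau, mV), Δamil (amiloride − Ringer) and TCR
(isoproterenol − amiloride, i.e. the summed chloride-free + isoproterenol
response). In CF, absent CFTR disinhibits ENaC (hyperpolarized PDmax, large
Δamil) and removes the chloride response (TCR ≈ 0); with working CFTR, TCR is
strongly negative.

## Plateau detection

The stability rule is the protocol's: a PD range strictly below `max_range`
(default 1 mV) sustained over a window of at least `window` seconds (default
30 s). `find_stable_plateau` selects, among all windows satisfying the rule,
the one with the **latest end time** (then the shortest, i.e. latest start),
and returns the **mean** PD over that window. The mean is a lower-variance
estimator of the same plateau that a single end-of-perfusion reading targets;
`endpoint=True` restores strict end-point semantics. For a given end time it
suffices to test the minimal-span window, because widening a window can only
increase its range; the unit tests nevertheless verify the detector against a
brute-force scan of every window. A phase with no stable window raises a
distinct `StabilityError` — the tracing is non-analyzable rather than
silently summarized, mirroring the practice of analyzing only stable
tracings.

Quality control gates on the electrode offset ("around zero", quantified
here as |offset| ≤ 2 mV — the protocol gives no number, so the tolerance is
configurable) and on skin PD, read as *more negative than* −30 mV at both
ends of the exam. The inequality direction of the skin criterion is
ambiguous in common phrasing ("magnitude < −30 mV"); this package fixes it
as skin_pd ≤ −30 mV, configurable.

The probe-positioning sweep that precedes the solution sequence is carried
as an optional `positioning` phase label but never analyzed: PDmax is defined
on the fixed-position Ringer phase.

## Scores and classification

`WI = exp(TCR/Δamil)` and `SS = −0.11·TCR − 0.05·Δamil`, with the package's
sign conventions (Δamil positive depolarization, TCR negative with CFTR
function). Cut-offs are applied verbatim on unrounded values: CF iff
WI > 0.7 (strict), CF iff SS ≤ 0.27; rounding (default 2 decimals) is
display-only. WI is undefined at Δamil ≤ 0 — such records are flagged, keep
their SS classification, and are never dropped. TCR categories: normal
< −12 mV, intermediate −12 to −7.7 mV, no function > −7.7 mV; the −12
boundary is assigned to intermediate (the source phrasing "between −12 and
−7.7" does not specify open/closed, so the choice is documented and the
exact boundary semantics tested). Historical single-parameter rules (Leal
secretor TCR < −5; Ho low-secretor |TCR| ≤ 10; Middleton |PDmax| > 30 with
|TCR| < 10) are exposed as optional named classifiers with the thresholds
translated into these sign conventions.

The bundled 11-patient CF reference table reproduces its printed WI/SS at
two decimals for 10 of 11 patients when recomputed from the printed integer
parameters; patient 1's printed scores derive from unrounded source
measurements and are deliberately not forced to agree.

## Group statistics

Summaries are mean, sample SD (n−1), t-based CI
(mean ± t<sub>1−α/2,n−1</sub>·sd/√n) and median with range. The t-based CI is
an inference from the published group CIs, which match t quantiles but not
normal quantiles at the printed precision (e.g. mean −31.7, SD 9.5, n 11 →
(−38.1, −25.3)). ANOVA, Levene (deviations from group means) and
Kruskal–Wallis delegate to scipy.stats. Scheffé pairwise contrasts are
implemented directly — no installed library exposes them — as
F<sub>ij</sub> = (x̄<sub>i</sub>−x̄<sub>j</sub>)² / ((k−1)·MSE·(1/n<sub>i</sub>+1/n<sub>j</sub>))
against F(k−1, N−k). Scheffé's validity is tested through exact reductions
(k = 2 equals the ANOVA F, which equals t²) and its defining conservativeness
(the Scheffé p never undercuts the unadjusted pooled-MSE contrast p); a raw
permutation of a single pairwise contrast was considered and rejected as an
oracle because it estimates the unadjusted p, not the simultaneous one.
Jonckheere–Terpstra ordered post-hocs are out of scope (no reference values
exist to validate against). Reported p-values below 0.001 are displayed as
"< 0.001", never as a literal zero.

## Repeatability

Bland–Altman on first vs second exams, differences fixed as
**first − second** and labelled as such in every output. Reported: n, mean
difference (bias), SD of differences (n−1), limits of agreement
mean ± 1.96·SD, a t-based 95% CI of the bias, and the pairs lying strictly
outside the limits. `plot_data()` returns the scatter (with identity line)
and mean-vs-difference series with the three reference lines; rendering is a
separate, optional matplotlib step. A regression-based proportional-bias
test is deliberately absent: agreement is assessed from the plots and limits,
and ICC/ISO repeatability coefficients are out of scope.

## The synthetic-data generator

The generator defines the study conditions used throughout the tests:

- **Group distributions** (defaults): independent Gaussians per parameter
  with the published group means (SD) — CF: PDmax −31.7 (9.5), Δamil 15
  (7.2), TCR −1.5 (5.8); non-CF: −16.4 (6.9), 7.5 (4.2), −15.3 (5.7);
  healthy: −15.2 (7.6), 7.8 (4.7), −13.0 (6.7); group sizes 11/19/48.
  No covariance is published, so parameters are drawn independently
  (configurable for sensitivity work). Δamil is truncated below at 0.5 mV so
  the WI exponent stays defined; non-positive amiloride responses are not
  observed in practice.
- **Repeat noise** (defaults): within-subject SDs calibrated from the
  published SDs of paired differences as sd_diff/√2 — PDmax 7.5/√2 ≈ 5.30 mV,
  TCR 7.81/√2 ≈ 5.52 mV; Δamil has no published calibration and defaults
  to 0.
- **Tracing shape**: 1 Hz sampling, 180 s phases, first-order exponential
  transitions (τ = 8 s), white noise 0.2 mV, optional linear drift. The noise
  default follows from the stability gate: the expected range of 30 iid
  N(0, σ) samples is ≈ 4.1σ, so σ = 0.2 mV keeps end-of-phase windows inside
  the 1 mV rule with high probability while σ = 0.3 would not. The TCR is
  split 70/30 between the chloride-free and isoproterenol plateaus; only the
  sum is diagnostically meaningful and the split is a configurable modelling
  choice with no published decomposition to match.

Randomness: one seed feeds a `SeedSequence`; each subject gets a spawned
substream, so cohorts are bit-reproducible and subjects are independent.

What the generator does **not** emulate: probe repositioning artifacts,
sneezes/motion spikes, electrode failure drift, non-Gaussian tails, and any
dependence between Δamil and TCR. Consequently, passing tests demonstrate
correctness of the pipeline's arithmetic and its statistical behavior under
the published summary model — not robustness to real-world artifacts. One
concrete consequence: under the independent-Gaussian model the group *mean*
of WI = exp(TCR/Δamil) is heavy-tailed (rare small-Δamil draws dominate it),
so simulation-based checks of group WI levels use the median, which
converges to exp(median TCR / median Δamil) ≈ 0.9 (CF) and ≈ 0.2 (healthy);
real cohorts do not show this divergence because near-zero Δamil with
positive TCR does not co-occur.

Statistical power is a property of these conditions, not a target: at the
published effect sizes and group sizes, ANOVA power at α = 0.001 is ≈ 1 for
PDmax and TCR but only ≈ 0.75 for Δamil (non-central F, λ ≈ 20), and the
test suite asserts exactly that behavior.

## Numerical and interface choices

- CSV everywhere (comma, dot decimal, UTF-8, mandatory header); tracing
  files carry `time_s, pd_mv, phase`, cohort files
  `subject_id, group, repeat_id, pdmax_mv, damil_mv, tcr_mv, wi, ss` (+
  class columns after scoring). Values round-trip to 6 decimals.
- Phase and group labels are closed enumerations with a documented synonym
  map (e.g. `lowCl` → `zero_chloride`, `non-CF` → `non_CF`).
- Time is seconds from tracing start; all computations are invariant to a
  constant time offset.
- The reader enforces structural invariants only; protocol completeness
  (four solution phases, ≥ 180 s each, in order) is enforced at extraction so
  partial tracings remain inspectable.
- Degenerate inputs: constant samples give SD 0 and a zero-width CI;
  identical groups give F = 0, p = 1; fewer than two observations (or pairs)
  raise `InsufficientDataError`.

## Problem sizes used in the validation suite

Exact reproductions run on the 11-patient reference table. Simulation-based
checks use: a 3×4×5 grid of truths for the zero-noise identity; 50–100
seeded tracings for extraction error; 100 seeds × 22 pairs for repeatability
calibration; 5000 pairs for limits-of-agreement coverage; 60 seeded
78-subject cohorts for power; and up to 8000 subjects for large-n
distributional checks. These sizes give Monte-Carlo error comfortably inside
the asserted tolerances.

## Known limitations

- Phases must be pre-annotated; no automatic phase-boundary inference.
- No artifact/spike removal; unstable phases are rejected, not repaired.
- The proprietary voltmeter export format is not parsed; tracings enter as
  CSV.
- Published limits of agreement cannot be reproduced digit-for-digit from
  printed rounded summaries; repeatability validation therefore targets the
  calibrated structural quantities (SD of differences, coverage, outside-LoA
  counts).
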