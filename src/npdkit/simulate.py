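"""Synthetic NPD cohorts and voltage tracings with known ground truth.

The generator emulates a three-arm study: CF patients, non-CF patients with
respiratory disease, and healthy volunteers.  Subject-level true parameters
(PDmax, Δamil, TCR) are drawn from group-specific Gaussians whose defaults
are the published group means and SDs (11/19/48 subjects); repeat
measurements add within-subject Gaussian noise whose default SDs are
calibrated to the published repeat-measurement Bland–Altman SDs of the
first-minus-second differences (7.5 mV for PDmax, 7.81 mV for TCR) via
``sd_within = sd_diff / √2`` (the difference of two iid repeats has variance
``2·σ²_within``).

Full tracings are piecewise plateaus joined by first-order exponential
transitions: Ringer at PDmax, amiloride at PDmax + Δamil, then the chloride
response split between the chloride-free and isoproterenol plateaus so the
final plateau sits at PDmax + Δamil + TCR.  Additive white Gaussian noise and
an optional linear drift complete the signal.

All randomness flows from a single seed through per-subject
``numpy.random.SeedSequence`` substreams, so identical seed and configuration
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .extraction import NpdParameters
from .io import CohortTable, Phase, QcRecord, SubjectRecord, Tracing, TracingPoint

__all__ = [
    "GroupDistribution",
    "RepeatNoise",
    "TracingShape",
    "SimulatedCohort",
    "DEFAULT_GROUP_DISTRIBUTIONS",
    "DEFAULT_SIZES",
    "simulate_cohort",
    "simulate_tracing",
    "load_config",
]


@dataclass(frozen=True)
class GroupDistribution:
    """Gaussian parameter distribution for one cohort group (all mV)."""

    group: str
    pdmax_mean: float
    pdmax_sd: float
    damil_mean: float
    damil_sd: float
    tcr_mean: float
    tcr_sd: float

    def __post_init__(self) -> None:
        for name in ("pdmax_sd", "damil_sd", "tcr_sd"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")


#: Published group means (SD): the study conditions the simulator reproduces.
DEFAULT_GROUP_DISTRIBUTIONS: dict[str, GroupDistribution] = {
    "CF": GroupDistribution("CF", -31.7, 9.5, 15.0, 7.2, -1.5, 5.8),
    "non_CF": GroupDistribution("non_CF", -16.4, 6.9, 7.5, 4.2, -15.3, 5.7),
    "healthy": GroupDistribution("healthy", -15.2, 7.6, 7.8, 4.7, -13.0, 6.7),
}

#: Published group sizes (CF, non-CF, healthy volunteers) = 78 subjects.
DEFAULT_SIZES: dict[str, int] = {"CF": 11, "non_CF": 19, "healthy": 48}

#: Δamil draws are truncated below at this value (mV) so the Wilschanski
#: exponent TCR/Δamil stays defined; non-positive amiloride responses are
#: never reported in practice.
DAMIL_FLOOR = 0.5


@dataclass(frozen=True)
class RepeatNoise:
    """Within-subject measurement SDs (mV).

    Defaults derive from the published Bland–Altman SDs of first-minus-second
    differences (7.5 for PDmax, 7.81 for TCR) as ``sd_diff / √2``.  Δamil
    within-subject noise defaults to zero (no published calibration exists);
    set it for sensitivity analyses.
    """

    within_subject_sd_pdmax: float = 7.5 / math.sqrt(2.0)
    within_subject_sd_tcr: float = 7.81 / math.sqrt(2.0)
    within_subject_sd_damil: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "within_subject_sd_pdmax",
            "within_subject_sd_tcr",
            "within_subject_sd_damil",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TracingShape:
    """Waveform parameters of a simulated tracing.

    ``chloride_split`` is the fraction of TCR realized during the
    chloride-free phase, the remainder during isoproterenol; only their sum is
    diagnostically meaningful, the split is a modelling knob.
    """

    sample_interval: float = 1.0
    phase_duration: float = 180.0
    transition_tau: float = 8.0
    noise_sd: float = 0.2
    drift_per_min: float = 0.0
    chloride_split: float = 0.7

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ParameterError("sample_interval must be > 0")
        if self.transition_tau <= 0:
            raise ParameterError("transition_tau must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.chloride_split <= 1.0:
            raise ParameterError("chloride_split must be in [0, 1]")

    def validate_against(self, stability_window: float = 30.0) -> None:
        if self.phase_duration < stability_window:
            raise ParameterError(
                f"phase_duration {self.phase_duration:g} s shorter than the "
                f"stability window {stability_window:g} s"
            )


@dataclass
class SimulatedCohort:
    """Observed cohort plus the subject-level ground truth it was drawn from."""

    cohort: CohortTable
    truth: pd.DataFrame  # columns: subject_id, group, pdmax, damil, tcr


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    # rejection sampling keeps the per-subject stream deterministic
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    raise ParameterError(
        f"truncation bound {lower} unreachable for N({mean}, {sd}^2)"
    )


def simulate_cohort(
    sizes: Mapping[str, int] | None = None,
    dists: Mapping[str, GroupDistribution] | None = None,
    repeats: int = 1,
    noise: RepeatNoise | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Draw a cohort of subjects with ``repeats`` measurements each.

    Subject truths come from the group Gaussians (Δamil truncated below at
    ``DAMIL_FLOOR``); each observed repeat adds within-subject Gaussian noise.
    PDmax and Δamil are drawn independently (no published covariance).
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    dists = dict(DEFAULT_GROUP_DISTRIBUTIONS if dists is None else dists)
    noise = noise or RepeatNoise()
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    for g, n in sizes.items():
        if n < 1:
            raise ParameterError(f"group {g} size must be >= 1, got {n}")
        if g not in dists:
            raise ParameterError(f"no distribution configured for group {g}")

    root = np.random.SeedSequence(seed)
    children = root.spawn(sum(sizes.values()))
    records: list[SubjectRecord] = []
    truth_rows: list[dict] = []
    k = 0
    for group in sizes:
        d = dists[group]
        for i in range(sizes[group]):
            rng = np.random.default_rng(children[k])
            k += 1
            sid = f"{group}{i + 1:03d}"
            pdmax = rng.normal(d.pdmax_mean, d.pdmax_sd)
            damil = _truncated_normal(rng, d.damil_mean, d.damil_sd, DAMIL_FLOOR)
            tcr = rng.normal(d.tcr_mean, d.tcr_sd)
            truth_rows.append(
                {"subject_id": sid, "group": group, "pdmax": pdmax, "damil": damil, "tcr": tcr}
            )
            for r in range(1, repeats + 1):
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        group=group,
                        repeat_id=r,
                        pdmax=pdmax + rng.normal(0.0, noise.within_subject_sd_pdmax)
                        if noise.within_subject_sd_pdmax > 0
                        else pdmax,
                        damil=max(
                            DAMIL_FLOOR,
                            damil + rng.normal(0.0, noise.within_subject_sd_damil),
                        )
                        if noise.within_subject_sd_damil > 0
                        else damil,
                        tcr=tcr + rng.normal(0.0, noise.within_subject_sd_tcr)
                        if noise.within_subject_sd_tcr > 0
                        else tcr,
                    )
                )
    return SimulatedCohort(
        cohort=CohortTable(records),
        truth=pd.DataFrame(truth_rows, columns=["subject_id", "group", "pdmax", "damil", "tcr"]),
    )


def simulate_tracing(
    truth: NpdParameters | tuple[float, float, float],
    shape: TracingShape = TracingShape(),
    seed: int = 0,
    subject_id: str = "sim",
    repeat_id: int = 1,
    qc: QcRecord | None = None,
    stability_window: float = 30.0,
) -> Tracing:
    """Synthesize a full four-phase tracing realizing the given true parameters.

    Plateau levels: Ringer = PDmax; amiloride = PDmax + Δamil; chloride-free =
    amiloride level + ``chloride_split``·TCR; isoproterenol = PDmax + Δamil +
    TCR.  Phase transitions follow first-order exponentials with time constant
    ``transition_tau`` starting from the previous phase's deterministic end
    value; white noise (``noise_sd``) and linear drift are added on top.  With
    zero noise and default durations the end-of-phase plateaus equal the
    targets to ~1e-7 mV, so extraction recovers the truth essentially exactly.
    """
    if isinstance(truth, NpdParameters):
        pdmax, damil, tcr = truth.pdmax, truth.damil, truth.tcr
    else:
        pdmax, damil, tcr = (float(v) for v in truth)
    shape.validate_against(stability_window)
    rng = np.random.default_rng(seed)

    levels = [
        (Phase.RINGER, pdmax),
        (Phase.AMILORIDE, pdmax + damil),
        (Phase.ZERO_CHLORIDE, pdmax + damil + shape.chloride_split * tcr),
        (Phase.ISOPROTERENOL, pdmax + damil + tcr),
    ]
    # each phase carries samples at local offsets 0 .. phase_duration inclusive,
    # so the sampled span equals the perfusion duration
    n_per_phase = int(round(shape.phase_duration / shape.sample_interval))
    points: list[TracingPoint] = []
    prev_end = 0.0  # electrode reads ~0 mV before the mucosal seal forms
    t_start = 0.0
    for phase, target in levels:
        local = np.arange(0, n_per_phase + 1) * shape.sample_interval
        clean = target + (prev_end - target) * np.exp(-local / shape.transition_tau)
        times = t_start + local
        values = clean + shape.drift_per_min * times / 60.0
        if shape.noise_sd > 0:
            values = values + rng.normal(0.0, shape.noise_sd, size=len(values))
        points.extend(
            TracingPoint(float(t), float(v), phase) for t, v in zip(times, values)
        )
        prev_end = float(clean[-1])
        t_start = float(times[-1]) + shape.sample_interval
    if qc is None:
        qc = QcRecord(0.0, 0.0, -45.0, -45.0)
    return Tracing(subject_id=subject_id, repeat_id=repeat_id, points=points, qc=qc)


def load_config(path: str | Path) -> dict:
    """Load a YAML simulation config with optional ``groups``, ``noise``,
    ``shape``, ``sizes``, ``repeats`` sections; returns simulate_* kwargs."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    if "sizes" in raw:
        out["sizes"] = {str(g): int(n) for g, n in raw["sizes"].items()}
    if "groups" in raw:
        out["dists"] = {
            str(g): GroupDistribution(group=str(g), **vals)
            for g, vals in raw["groups"].items()
        }
    if "noise" in raw:
        out["noise"] = RepeatNoise(**raw["noise"])
    if "repeats" in raw:
        out["repeats"] = int(raw["repeats"])
    shape = TracingShape(**raw["shape"]) if "shape" in raw else TracingShape()
    out["shape"] = shape
    return out
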