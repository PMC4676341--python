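"""Plateau detection and NPD parameter extraction.

The protocol requires each perfusion phase to end on a stable plateau —
a change of less than 1 mV sustained for at least 30 s — before the next
solution is started.  Parameters are read off the end-of-phase plateaus:

* ``PDmax``  = plateau(Ringer), the maximal basal PD (most negative);
* ``Δamil``  = plateau(amiloride) − plateau(Ringer), the ENaC-blocker
  depolarization (positive);
* ``TCR``    = plateau(isoproterenol) − plateau(amiloride), the total
  chloride response summed over the chloride-free and isoproterenol
  perfusions (strongly negative with working CFTR, near zero in CF).

The plateau value is the mean PD over the detected stable window — a
lower-variance estimator of the same plateau the end-of-perfusion reading
targets; ``endpoint=True`` switches to the final sample for strict
end-point semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ProtocolError, StabilityError
from .io import Phase, QcRecord, SOLUTION_PHASES, Tracing, TracingPoint

__all__ = [
    "StabilityRule",
    "NpdParameters",
    "QcVerdict",
    "find_stable_plateau",
    "extract_parameters",
    "check_qc",
]


@dataclass(frozen=True)
class StabilityRule:
    """End-of-phase stability gate: PD range < ``max_range`` mV over a window
    of at least ``window`` seconds."""

    window: float = 30.0
    max_range: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ParameterError(f"window must be > 0, got {self.window}")
        if self.max_range <= 0:
            raise ParameterError(f"max_range must be > 0, got {self.max_range}")


@dataclass
class NpdParameters:
    """Extracted NPD parameters (mV) plus per-phase plateau values and QC verdict."""

    pdmax: float
    damil: float
    tcr: float
    plateau_values: dict[Phase, float] = field(default_factory=dict)
    qc_pass: bool | None = None


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


def find_stable_plateau(
    points: list[TracingPoint],
    rule: StabilityRule = StabilityRule(),
    endpoint: bool = False,
) -> float:
    """Locate the latest stable window within one phase and return its plateau.

    A window is stable when it spans at least ``rule.window`` seconds and its
    PD range (max − min) is strictly below ``rule.max_range``.  Among stable
    windows the one with the latest end time is chosen, and among those the
    shortest (latest start).  Returns the mean PD over that window, or the
    final sample of it when ``endpoint`` is set.

    Raises :class:`StabilityError` when no stable window exists (the tracing
    phase is non-analyzable).
    """
    times = np.asarray([p.time for p in points], dtype=float)
    pds = np.asarray([p.pd for p in points], dtype=float)
    n = len(points)
    if n == 0 or times[-1] - times[0] < rule.window:
        raise StabilityError(
            f"phase span {0.0 if n == 0 else times[-1] - times[0]:.1f} s "
            f"shorter than stability window {rule.window:.1f} s"
        )
    # scan ends from latest to earliest; for each end take the shortest
    # window reaching the required span
    for j in range(n - 1, -1, -1):
        i = int(np.searchsorted(times, times[j] - rule.window, side="right")) - 1
        if i < 0 or times[j] - times[i] < rule.window:
            break  # no earlier end can span the window either
        seg = pds[i : j + 1]
        if seg.max() - seg.min() < rule.max_range:
            return float(seg[-1]) if endpoint else float(seg.mean())
    raise StabilityError(
        f"no window of {rule.window:.0f} s with PD range < {rule.max_range:g} mV"
    )


def check_qc(
    qc: QcRecord,
    offset_tolerance: float = 2.0,
    skin_threshold: float = -30.0,
) -> QcVerdict:
    """Quality-control gate on electrode offsets and skin PD.

    Passes when both electrode offsets are within ``offset_tolerance`` of zero
    (the protocol requires offsets "around zero"; the default quantifies that
    as ±2 mV) and both skin PD readings are at least as negative as
    ``skin_threshold`` (default −30 mV).
    """
    reasons: list[str] = []
    for label, off in (("start", qc.offset_start), ("end", qc.offset_end)):
        if abs(off) > offset_tolerance:
            reasons.append(
                f"electrode offset at {label} ({off:+.1f} mV) exceeds "
                f"±{offset_tolerance:g} mV"
            )
    for label, skin in (("start", qc.skin_pd_start), ("end", qc.skin_pd_end)):
        if skin > skin_threshold:
            reasons.append(
                f"skin PD above threshold at {label} ({skin:.1f} mV > "
                f"{skin_threshold:g} mV)"
            )
    return QcVerdict(passed=not reasons, reasons=tuple(reasons))


def extract_parameters(
    t: Tracing,
    rule: StabilityRule = StabilityRule(),
    min_phase_duration: float = 180.0,
    offset_tolerance: float = 2.0,
    skin_threshold: float = -30.0,
    endpoint: bool = False,
) -> NpdParameters:
    """Extract PDmax, Δamil and TCR from a tracing.

    Requires the four solution phases in protocol order (ProtocolError
    otherwise); any phase without a stable end window raises StabilityError.
    A positive PDmax is physiologically unexpected and triggers a warning,
    not an error.
    """
    t.require_protocol(min_phase_duration)
    plateaus: dict[Phase, float] = {}
    for phase in SOLUTION_PHASES:
        pts = t.phase_points(phase)
        try:
            plateaus[phase] = find_stable_plateau(pts, rule, endpoint=endpoint)
        except StabilityError as exc:
            raise StabilityError(f"phase {phase.value}: {exc}") from None
    pdmax = plateaus[Phase.RINGER]
    damil = plateaus[Phase.AMILORIDE] - pdmax
    tcr = plateaus[Phase.ISOPROTERENOL] - plateaus[Phase.AMILORIDE]
    if pdmax > 0:
        warnings.warn(
            f"{t.subject_id} repeat {t.repeat_id}: positive basal PD "
            f"({pdmax:.1f} mV) is physiologically unexpected",
            stacklevel=2,
        )
    qc_pass = (
        bool(check_qc(t.qc, offset_tolerance, skin_threshold))
        if t.qc is not None
        else None
    )
    return NpdParameters(
        pdmax=pdmax, damil=damil, tcr=tcr, plateau_values=plateaus, qc_pass=qc_pass
    )
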