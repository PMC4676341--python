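"""Diagnostic scores and CF classification from NPD parameters.

Two published composite scores combine the sodium (Δamil) and chloride (TCR)
transport readouts of the NPD test:

* Wilschanski index  ``WI = exp(TCR / Δamil)`` — CF when WI > 0.7.
  Undefined for Δamil ≤ 0 (the exponent is singular at zero).
* Sermet score       ``SS = −0.11·TCR − 0.05·Δamil`` — CF when SS ≤ 0.27.

Sign conventions: Δamil is the depolarizing amiloride response (positive),
TCR the hyperpolarizing chloride response (negative with working CFTR, near
zero or positive in CF).  Residual-CFTR-function categories on TCR alone:
normal when TCR < −12 mV, intermediate when −12 ≤ TCR ≤ −7.7 mV (the
boundary −12 is assigned to intermediate), no function when TCR > −7.7 mV.

Classification always uses unrounded values; rounding is for display only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from dataclasses import replace as _replace

from .errors import UndefinedScoreError
from .extraction import NpdParameters
from .io import CohortTable

__all__ = [
    "WI_CUTOFF",
    "SS_CUTOFF",
    "TCR_NORMAL_BOUND",
    "TCR_NO_FUNCTION_BOUND",
    "DiagnosticScores",
    "wilschanski_index",
    "sermet_score",
    "classify",
    "tcr_category",
    "score_parameters",
    "score_cohort",
    "leal_secretor_class",
    "ho_secretor_class",
    "middleton_cf_class",
]

#: CF predicted when the Wilschanski index strictly exceeds this value.
WI_CUTOFF = 0.7
#: CF predicted when the Sermet score is at or below this value.
SS_CUTOFF = 0.27
#: TCR below this (mV) indicates normal CFTR function.
TCR_NORMAL_BOUND = -12.0
#: TCR above this (mV) indicates no CFTR function; [-12, -7.7] is intermediate.
TCR_NO_FUNCTION_BOUND = -7.7


@dataclass(frozen=True)
class DiagnosticScores:
    """Scores and categorical calls for one set of NPD parameters.

    ``wi`` and ``wi_class`` are ``None`` when Δamil ≤ 0 (index undefined);
    the Sermet score is always defined.
    """

    wi: float | None
    ss: float
    wi_class: str | None
    ss_class: str
    tcr_category: str


def _damil_tcr(p) -> tuple[float, float]:
    if isinstance(p, NpdParameters):
        return p.damil, p.tcr
    damil, tcr = p
    return float(damil), float(tcr)


def wilschanski_index(p: NpdParameters | tuple[float, float]) -> float:
    """``exp(TCR / Δamil)``; raises :class:`UndefinedScoreError` if Δamil ≤ 0.

    Accepts :class:`NpdParameters` or a ``(damil, tcr)`` pair.
    """
    damil, tcr = _damil_tcr(p)
    if damil <= 0:
        raise UndefinedScoreError(
            f"Wilschanski index undefined for Δamil = {damil:g} mV (requires > 0)",
            value=damil,
        )
    return math.exp(tcr / damil)


def sermet_score(p: NpdParameters | tuple[float, float]) -> float:
    """``−0.11·TCR − 0.05·Δamil``; defined for all parameter values."""
    damil, tcr = _damil_tcr(p)
    return -(0.11 * tcr) - (0.05 * damil)


def tcr_category(tcr: float) -> str:
    """Residual-CFTR-function category from TCR alone (mV)."""
    if tcr < TCR_NORMAL_BOUND:
        return "normal"
    if tcr <= TCR_NO_FUNCTION_BOUND:
        return "intermediate"
    return "no_function"


def classify(wi: float | None, ss: float, tcr: float) -> tuple[str | None, str, str]:
    """Apply the published cut-offs; returns (wi_class, ss_class, tcr_category).

    Boundary semantics are exact: WI = 0.7 → non_CF (strict >), SS = 0.27 → CF
    (≤), TCR = −7.7 → intermediate.  An undefined WI yields wi_class ``None``
    while the SS classification is still produced.
    """
    wi_class = None if wi is None else ("CF" if wi > WI_CUTOFF else "non_CF")
    ss_class = "CF" if ss <= SS_CUTOFF else "non_CF"
    return wi_class, ss_class, tcr_category(tcr)


def score_parameters(p: NpdParameters | tuple[float, float]) -> DiagnosticScores:
    """Compute both scores and all categorical calls for one parameter set."""
    damil, tcr = _damil_tcr(p)
    try:
        wi = wilschanski_index((damil, tcr))
    except UndefinedScoreError:
        wi = None
    ss = sermet_score((damil, tcr))
    wi_class, ss_class, cat = classify(wi, ss, tcr)
    return DiagnosticScores(
        wi=wi, ss=ss, wi_class=wi_class, ss_class=ss_class, tcr_category=cat
    )


def score_cohort(table: CohortTable) -> CohortTable:
    """Return a new cohort table with scores and classes filled in.

    Records with Δamil ≤ 0 keep ``wi = None`` and are flagged with a warning
    listing the affected (subject, repeat) keys; they are never dropped.
    """
    flagged: list[tuple[str, int]] = []
    records = []
    for r in table:
        if r.damil is None or r.tcr is None:
            records.append(r)
            continue
        s = score_parameters((r.damil, r.tcr))
        if s.wi is None:
            flagged.append((r.subject_id, r.repeat_id))
        records.append(
            _replace(
                r,
                wi=s.wi,
                ss=s.ss,
                wi_class=s.wi_class,
                ss_class=s.ss_class,
                tcr_category=s.tcr_category,
            )
        )
    if flagged:
        warnings.warn(
            f"Wilschanski index undefined (Δamil ≤ 0) for {len(flagged)} "
            f"record(s): {flagged}",
            stacklevel=2,
        )
    return CohortTable(records)


# ---------------------------------------------------------------------------
# Additional published TCR/PDmax classifiers (optional, named)
# ---------------------------------------------------------------------------
# These historical rules are quoted in the CF literature with varying sign
# conventions; here all thresholds use this package's convention (PD in mV,
# hyperpolarization negative), with the magnitude-based originals translated
# accordingly.


def leal_secretor_class(tcr: float) -> str:
    """Secretor when TCR < −5 mV, non-secretor otherwise."""
    return "secretor" if tcr < -5.0 else "non_secretor"


def ho_secretor_class(tcr: float) -> str:
    """Low chloride secretor when |TCR| ≤ 10 mV, high secretor otherwise."""
    return "low_secretor" if abs(tcr) <= 10.0 else "high_secretor"


def middleton_cf_class(pdmax: float, tcr: float) -> str:
    """CF when |PDmax| > 30 mV and |TCR| < 10 mV, non-CF otherwise."""
    return "CF" if (abs(pdmax) > 30.0 and abs(tcr) < 10.0) else "non_CF"
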