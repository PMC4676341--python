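"""Data model and CSV interchange for NPD tracings and cohort tables.

A *tracing* is one subject's transepithelial potential difference (PD, mV)
recorded against time while the nasal mucosa is perfused with a fixed sequence
of solutions: Ringer's (basal), amiloride (ENaC blocker), chloride-free +
amiloride, and chloride-free + amiloride + isoproterenol.  A *cohort table*
holds one row per (subject, repeat) with the extracted NPD parameters and,
once computed, the diagnostic scores.

CSV dialects are fixed: comma-separated, dot decimal, UTF-8, mandatory header.

Tracing CSV columns:  ``time_s, pd_mv, phase``
Cohort CSV columns:   ``subject_id, group, repeat_id, pdmax_mv, damil_mv,
tcr_mv, wi, ss`` (``wi``/``ss`` may be blank before scoring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import DataError, FormatError, ProtocolError

__all__ = [
    "Phase",
    "SOLUTION_PHASES",
    "normalize_phase",
    "normalize_group",
    "GROUPS",
    "TracingPoint",
    "QcRecord",
    "Tracing",
    "SubjectRecord",
    "CohortTable",
    "read_tracing",
    "write_tracing",
    "read_cohort",
    "write_cohort",
]


class Phase(str, Enum):
    """Perfusion phases of the NPD protocol, in order."""

    POSITIONING = "positioning"
    RINGER = "ringer"
    AMILORIDE = "amiloride"
    ZERO_CHLORIDE = "zero_chloride"
    ISOPROTERENOL = "isoproterenol"


#: The four solution phases required for parameter extraction, in protocol order.
SOLUTION_PHASES: tuple[Phase, ...] = (
    Phase.RINGER,
    Phase.AMILORIDE,
    Phase.ZERO_CHLORIDE,
    Phase.ISOPROTERENOL,
)

# Synonyms seen in hand-labelled exports; keys are casefolded with separators
# collapsed to "_".  The canonical labels themselves always round-trip.
_PHASE_SYNONYMS: dict[str, Phase] = {
    "positioning": Phase.POSITIONING,
    "position": Phase.POSITIONING,
    "ringer": Phase.RINGER,
    "ringers": Phase.RINGER,
    "basal": Phase.RINGER,
    "amiloride": Phase.AMILORIDE,
    "amil": Phase.AMILORIDE,
    "zero_chloride": Phase.ZERO_CHLORIDE,
    "zerochloride": Phase.ZERO_CHLORIDE,
    "zero_cl": Phase.ZERO_CHLORIDE,
    "0cl": Phase.ZERO_CHLORIDE,
    "lowcl": Phase.ZERO_CHLORIDE,
    "low_cl": Phase.ZERO_CHLORIDE,
    "chloride_free": Phase.ZERO_CHLORIDE,
    "cl_free": Phase.ZERO_CHLORIDE,
    "isoproterenol": Phase.ISOPROTERENOL,
    "iso": Phase.ISOPROTERENOL,
    "isoprenaline": Phase.ISOPROTERENOL,
}

#: Canonical cohort group labels.
GROUPS: tuple[str, ...] = ("CF", "non_CF", "healthy")

_GROUP_SYNONYMS: dict[str, str] = {
    "cf": "CF",
    "non_cf": "non_CF",
    "noncf": "non_CF",
    "healthy": "healthy",
    "healthy_volunteer": "healthy",
    "healthy_volunteers": "healthy",
    "hv": "healthy",
}


def _canon_key(label: str) -> str:
    return label.strip().casefold().replace("-", "_").replace(" ", "_")


def normalize_phase(label: str) -> Phase:
    """Map a phase label (or documented synonym) to its canonical :class:`Phase`.

    Raises :class:`~npdkit.errors.DataError` for unknown labels.
    """
    try:
        return _PHASE_SYNONYMS[_canon_key(str(label))]
    except KeyError:
        raise DataError(f"unknown phase label: {label!r}") from None


def normalize_group(label: str) -> str:
    """Map a group label (or documented synonym) to CF / non_CF / healthy."""
    try:
        return _GROUP_SYNONYMS[_canon_key(str(label))]
    except KeyError:
        raise DataError(f"unknown group label: {label!r}") from None


@dataclass(frozen=True)
class TracingPoint:
    """One voltmeter sample: time from tracing start (s), PD (mV), phase label."""

    time: float
    pd: float
    phase: Phase

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"negative time: {self.time}")


@dataclass(frozen=True)
class QcRecord:
    """Electrode-offset and skin-PD quality-control readings taken at the
    beginning and end of the procedure (all mV)."""

    offset_start: float
    offset_end: float
    skin_pd_start: float
    skin_pd_end: float


@dataclass
class Tracing:
    """One subject's voltage time-series with phase annotations.

    The reader enforces only structural invariants (strictly increasing time,
    known phases).  Protocol completeness — the four solution phases present
    contiguously in order, each spanning a minimum duration — is checked by
    :meth:`check_protocol` and enforced at extraction time, so that partial
    tracings can still be inspected.
    """

    subject_id: str
    repeat_id: int
    points: list[TracingPoint]
    qc: QcRecord | None = None

    def __post_init__(self) -> None:
        if self.repeat_id < 1:
            raise DataError(f"repeat_id must be >= 1, got {self.repeat_id}")
        times = [p.time for p in self.points]
        for a, b in zip(times, times[1:]):
            if b <= a:
                raise DataError(f"time not strictly increasing at t={b}")

    def phase_points(self, phase: Phase) -> list[TracingPoint]:
        return [p for p in self.points if p.phase is phase]

    def check_protocol(self, min_phase_duration: float = 180.0) -> list[str]:
        """Return a list of protocol violations (empty if compliant).

        Checks: the four solution phases all present, contiguous, in protocol
        order, and each spanning at least ``min_phase_duration`` seconds
        (the protocol perfuses each solution for at least 3 min).
        """
        problems: list[str] = []
        seq = [p.phase for p in self.points if p.phase is not Phase.POSITIONING]
        # contiguity + order: the deduplicated sequence must be a subsequence
        # of the protocol order with no revisits
        dedup: list[Phase] = []
        for ph in seq:
            if not dedup or dedup[-1] is not ph:
                dedup.append(ph)
        if len(set(dedup)) != len(dedup):
            problems.append("a phase is revisited (phases must be contiguous)")
        order = [ph for ph in SOLUTION_PHASES if ph in dedup]
        if [ph for ph in dedup if ph in SOLUTION_PHASES] != order:
            problems.append("solution phases out of protocol order")
        for ph in SOLUTION_PHASES:
            pts = self.phase_points(ph)
            if not pts:
                problems.append(f"missing phase: {ph.value}")
            elif pts[-1].time - pts[0].time < min_phase_duration:
                problems.append(
                    f"phase {ph.value} spans "
                    f"{pts[-1].time - pts[0].time:.0f} s < {min_phase_duration:.0f} s"
                )
        return problems

    def require_protocol(self, min_phase_duration: float = 180.0) -> None:
        problems = self.check_protocol(min_phase_duration)
        if problems:
            raise ProtocolError("; ".join(problems))


@dataclass
class SubjectRecord:
    """One (subject, repeat) row of a cohort table.

    Parameters and scores are stored flat, mirroring the cohort CSV columns;
    they are ``None`` until extracted/computed.  ``wi_class``, ``ss_class``
    and ``tcr_category`` are filled by scoring and written as extra columns.
    """

    subject_id: str
    group: str
    repeat_id: int
    pdmax: float | None = None
    damil: float | None = None
    tcr: float | None = None
    wi: float | None = None
    ss: float | None = None
    wi_class: str | None = None
    ss_class: str | None = None
    tcr_category: str | None = None

    def __post_init__(self) -> None:
        self.group = normalize_group(self.group)
        if self.repeat_id < 1:
            raise DataError(f"repeat_id must be >= 1, got {self.repeat_id}")


_COHORT_BASE_COLS = [
    "subject_id",
    "group",
    "repeat_id",
    "pdmax_mv",
    "damil_mv",
    "tcr_mv",
    "wi",
    "ss",
]
_COHORT_EXTRA_COLS = ["wi_class", "ss_class", "tcr_category"]
_FIELD_BY_COL = {
    "pdmax_mv": "pdmax",
    "damil_mv": "damil",
    "tcr_mv": "tcr",
    "wi": "wi",
    "ss": "ss",
    "wi_class": "wi_class",
    "ss_class": "ss_class",
    "tcr_category": "tcr_category",
}


@dataclass
class CohortTable:
    """Subjects x (group, repeat, parameters, scores); (subject_id, repeat_id) unique."""

    records: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.subject_id, r.repeat_id) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DataError(f"duplicate (subject_id, repeat_id): {dupes}")
        by_subject: dict[str, str] = {}
        for r in self.records:
            prev = by_subject.setdefault(r.subject_id, r.group)
            if prev != r.group:
                raise DataError(
                    f"subject {r.subject_id} has inconsistent group labels "
                    f"({prev} vs {r.group})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "repeat_id": r.repeat_id,
                    "pdmax_mv": r.pdmax,
                    "damil_mv": r.damil,
                    "tcr_mv": r.tcr,
                    "wi": r.wi,
                    "ss": r.ss,
                    "wi_class": r.wi_class,
                    "ss_class": r.ss_class,
                    "tcr_category": r.tcr_category,
                }
            )
        df = pd.DataFrame(rows, columns=_COHORT_BASE_COLS + _COHORT_EXTRA_COLS)
        if df[_COHORT_EXTRA_COLS].isna().all().all():
            df = df[_COHORT_BASE_COLS]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        missing = [c for c in _COHORT_BASE_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing columns: {missing}")
        records = []
        for row in df.itertuples(index=False):
            kwargs = {}
            for col, fld in _FIELD_BY_COL.items():
                if col not in df.columns:
                    continue
                v = getattr(row, col)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    kwargs[fld] = None
                else:
                    kwargs[fld] = v
            records.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    group=str(row.group),
                    repeat_id=int(row.repeat_id),
                    **kwargs,
                )
            )
        return cls(records)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_TRACING_COLS = ["time_s", "pd_mv", "phase"]


def read_tracing(
    path: str | Path,
    subject_id: str | None = None,
    repeat_id: int = 1,
    qc: QcRecord | None = None,
) -> Tracing:
    """Read a tracing CSV (columns ``time_s, pd_mv, phase``).

    ``subject_id`` defaults to the file stem.  Rows are preserved in file
    order; a missing column raises :class:`FormatError`, non-increasing time
    or an unknown phase label raises :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRACING_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    points = [
        TracingPoint(float(t), float(v), normalize_phase(ph))
        for t, v, ph in zip(df["time_s"], df["pd_mv"], df["phase"])
    ]
    return Tracing(
        subject_id=subject_id if subject_id is not None else path.stem,
        repeat_id=repeat_id,
        points=points,
        qc=qc,
    )


def write_tracing(t: Tracing, path: str | Path) -> Path:
    """Write a tracing as CSV with header ``time_s,pd_mv,phase``; returns the path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": [p.time for p in t.points],
            "pd_mv": [p.pd for p in t.points],
            "phase": [p.phase.value for p in t.points],
        },
        columns=_TRACING_COLS,
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable` (extra columns preserved
    when recognized, otherwise ignored)."""
    df = pd.read_csv(path)
    return CohortTable.from_dataframe(df)


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False, float_format="%.6f")
    return path
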