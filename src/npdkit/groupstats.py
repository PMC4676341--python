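"""Group summaries and between-group tests for NPD parameters and scores.

Summaries follow the reporting style of NPD cohort studies: mean with sample
SD (n−1 denominator), a t-based 95% confidence interval, and median with
range.  Between-group comparisons use one-way ANOVA with Scheffé post-hoc
pairwise contrasts, Levene's test (absolute deviations from the group means)
for variance homogeneity, and the Kruskal–Wallis rank test as the
non-parametric check.

The t-based CI (rather than a normal-quantile CI) is deliberate: at the small
group sizes typical of CF cohorts the two differ at the printed precision,
and published group CIs are consistent with t quantiles.

``GroupComparison`` wraps the whole analysis in a model object: build it from
a tidy DataFrame, call :meth:`~GroupComparison.fit`, read the results off the
returned :class:`GroupComparisonResults` (or print ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "one_way_anova",
    "scheffe_pairwise",
    "levene_test",
    "kruskal_wallis",
    "format_p",
    "GroupComparison",
    "GroupComparisonResults",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: tuple[float, ...] | None
    p_value: float
    pairwise: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ParameterError(f"p-value out of [0, 1]: {self.p_value}")


def format_p(p: float) -> str:
    """Report p-values without printing a literal zero."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def summarize(
    values: Sequence[float], confidence: float = 0.95, group: str = ""
) -> GroupSummary:
    """Mean, sample SD, t-based CI, and median with range for one group."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 observations, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1)) * sd / np.sqrt(n)
    return GroupSummary(
        group=group,
        n=n,
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        median=float(np.median(x)),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise InsufficientDataError(f"group {i} has n = {len(g)} < 2")
    return arrays


def one_way_anova(*groups: Sequence[float]) -> TestResult:
    """One-way ANOVA F test across k groups."""
    arrays = _check_groups(groups)
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    return TestResult(
        method="one-way ANOVA",
        statistic=float(f),
        df=(k - 1, n_total - k),
        p_value=float(p),
    )


def scheffe_pairwise(
    *groups: Sequence[float], labels: Sequence[str] | None = None
) -> TestResult:
    """Scheffé post-hoc test for all pairwise mean contrasts.

    For groups i, j the statistic is
    ``F_ij = (x̄_i − x̄_j)² / ((k−1) · MSE · (1/n_i + 1/n_j))``
    referred to the F(k−1, N−k) distribution, where MSE is the within-group
    mean square of the one-way ANOVA.  This is the classical simultaneous
    procedure: conservative for pairwise contrasts but valid for every linear
    contrast at once.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ParameterError("labels length must match number of groups")
    df_within = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in arrays) / df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[i].mean() - arrays[j].mean()
            if mse == 0:
                f_ij = 0.0 if diff == 0 else np.inf
            else:
                f_ij = diff**2 / ((k - 1) * mse * (1 / len(arrays[i]) + 1 / len(arrays[j])))
            p = float(stats.f.sf(f_ij, k - 1, df_within)) if np.isfinite(f_ij) else 0.0
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_diff": float(diff),
                    "statistic": float(f_ij),
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    worst = table.loc[table["p_value"].idxmin()]
    return TestResult(
        method="Scheffé post-hoc",
        statistic=float(worst["statistic"]),
        df=(k - 1, df_within),
        p_value=float(worst["p_value"]),
        pairwise=table,
    )


def levene_test(*groups: Sequence[float]) -> TestResult:
    """Levene's test for variance homogeneity (deviations from group means)."""
    arrays = _check_groups(groups)
    w, p = stats.levene(*arrays, center="mean")
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    return TestResult(
        method="Levene", statistic=float(w), df=(k - 1, n_total - k), p_value=float(p)
    )


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Kruskal–Wallis H test on ranks with tie correction."""
    arrays = _check_groups(groups)
    h, p = stats.kruskal(*arrays)
    return TestResult(
        method="Kruskal-Wallis", statistic=float(h), df=(len(arrays) - 1,), p_value=float(p)
    )


class GroupComparison:
    """Between-group comparison model for one measured variable.

    Parameters
    ----------
    groups : mapping of group label -> observations
    variable : name used in the summary output
    """

    def __init__(self, groups: Mapping[str, Sequence[float]], variable: str = "value"):
        if len(groups) < 2:
            raise InsufficientDataError("need at least 2 groups")
        self.groups = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
        self.variable = variable

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value: str, group: str = "group"
    ) -> "GroupComparison":
        """Build from a tidy DataFrame with one observation per row."""
        sub = df[[group, value]].dropna()
        groups = {str(g): v[value].to_numpy() for g, v in sub.groupby(group, sort=False)}
        return cls(groups, variable=value)

    def fit(self, confidence: float = 0.95) -> "GroupComparisonResults":
        labels = list(self.groups)
        arrays = [self.groups[g] for g in labels]
        summaries = [summarize(a, confidence, group=g) for g, a in zip(labels, arrays)]
        return GroupComparisonResults(
            variable=self.variable,
            summaries=summaries,
            anova=one_way_anova(*arrays),
            scheffe=scheffe_pairwise(*arrays, labels=labels),
            levene=levene_test(*arrays),
            kruskal=kruskal_wallis(*arrays),
            confidence=confidence,
        )


@dataclass
class GroupComparisonResults:
    """Per-group summaries plus omnibus, post-hoc and robustness tests."""

    variable: str
    summaries: list[GroupSummary]
    anova: TestResult
    scheffe: TestResult
    levene: TestResult
    kruskal: TestResult
    confidence: float = 0.95

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": s.group,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "median": s.median,
                    "min": s.minimum,
                    "max": s.maximum,
                }
                for s in self.summaries
            ]
        )

    def summary(self) -> str:
        pct = int(round(self.confidence * 100))
        lines = [f"Group comparison: {self.variable}", "=" * 40]
        for s in self.summaries:
            lines.append(
                f"{s.group:>12}  n={s.n:<3d} mean {s.mean:7.2f} (SD {s.sd:.2f})  "
                f"{pct}% CI ({s.ci_low:.1f} to {s.ci_high:.1f})  "
                f"median {s.median:.1f} [{s.minimum:.1f}, {s.maximum:.1f}]"
            )
        lines.append(
            f"One-way ANOVA: F({self.anova.df[0]:.0f}, {self.anova.df[1]:.0f}) = "
            f"{self.anova.statistic:.2f}, p = {format_p(self.anova.p_value)}"
        )
        lines.append(
            f"Levene: W = {self.levene.statistic:.2f}, p = {format_p(self.levene.p_value)};  "
            f"Kruskal-Wallis: H = {self.kruskal.statistic:.2f}, "
            f"p = {format_p(self.kruskal.p_value)}"
        )
        lines.append("Scheffé pairwise:")
        for row in self.scheffe.pairwise.itertuples(index=False):
            lines.append(
                f"  {row.group_1} vs {row.group_2}: diff {row.mean_diff:6.2f}, "
                f"p = {format_p(row.p_value)}"
            )
        return "\n".join(lines)
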