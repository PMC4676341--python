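"""Bland–Altman agreement analysis of repeated NPD measurements.

Two measurements of the same quantity on the same subjects (first and second
NPD exams) are compared through the differences ``d_i = first_i − second_i``
(the first-minus-second convention is fixed and stated in all outputs).  The
analysis reports the mean difference (bias), the SD of the differences
(sample SD, n−1 denominator), the 95% limits of agreement
``mean_diff ± 1.96·SD``, a t-based 95% CI for the mean difference, and which
pairs fall strictly outside the limits.  Under approximate normality ~95% of
differences are expected inside the limits.

``BlandAltman`` is the model object (build from paired arrays or a cohort
table with two repeats per subject); ``fit()`` returns
:class:`BlandAltmanResults` with the statistics, ``summary()``,
``plot_data()`` and an optional matplotlib ``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .io import CohortTable

__all__ = ["BlandAltman", "BlandAltmanResults", "bland_altman", "agreement_plot_data"]

#: Normal quantile used for the limits of agreement.
LOA_FACTOR = 1.96


@dataclass
class BlandAltmanResults:
    """Agreement statistics for one parameter across paired repeats.

    Differences are first − second throughout.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean_diff: tuple[float, float]
    outside_loa: int
    outside_ids: tuple[str, ...]
    first: np.ndarray = field(repr=False)
    second: np.ndarray = field(repr=False)
    ids: tuple[str, ...] = field(repr=False, default=())
    variable: str = "value"

    @property
    def differences(self) -> np.ndarray:
        return self.first - self.second

    @property
    def means(self) -> np.ndarray:
        return (self.first + self.second) / 2.0

    def plot_data(self) -> dict:
        """Plottable series for the scatter and Bland–Altman panels.

        ``scatter``: first vs second with the identity line; ``ba``: pairwise
        means vs differences with three reference lines (mean difference and
        the two limits of agreement).  No rendering happens here.
        """
        return {
            "scatter": {
                "first": self.first.copy(),
                "second": self.second.copy(),
                "identity": True,
            },
            "ba": {
                "mean": self.means,
                "diff": self.differences,
                "mean_diff": self.mean_diff,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
            },
        }

    def plot(self, axes=None):
        """Render the scatter + Bland–Altman panels (matplotlib)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4))
        ax0, ax1 = axes
        ax0.scatter(self.first, self.second, s=20, color="0.2")
        lims = [min(self.first.min(), self.second.min()), max(self.first.max(), self.second.max())]
        ax0.plot(lims, lims, ls=":", color="0.5", label="perfect agreement")
        ax0.set_xlabel(f"first {self.variable}")
        ax0.set_ylabel(f"second {self.variable}")
        ax0.legend(frameon=False)
        ax1.scatter(self.means, self.differences, s=20, color="0.2")
        ax1.axhline(self.mean_diff, ls="--", color="0.3", label="mean difference")
        for y in (self.loa_low, self.loa_high):
            ax1.axhline(y, ls="--", color="0.6")
        ax1.set_xlabel(f"mean of measurements ({self.variable})")
        ax1.set_ylabel("first − second")
        ax1.legend(frameon=False)
        return axes

    def summary(self) -> str:
        lo, hi = self.ci_mean_diff
        return "\n".join(
            [
                f"Bland-Altman agreement: {self.variable} (first − second), n = {self.n}",
                f"  mean difference {self.mean_diff:.2f} (SD {self.sd_diff:.2f}), "
                f"95% CI ({lo:.2f} to {hi:.2f})",
                f"  limits of agreement ({self.loa_low:.2f} to {self.loa_high:.2f})",
                f"  pairs outside limits: {self.outside_loa}"
                + (f" ({', '.join(self.outside_ids)})" if self.outside_ids else ""),
            ]
        )

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "direction": "first - second",
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ci_mean_diff": list(self.ci_mean_diff),
            "outside_loa": self.outside_loa,
            "outside_ids": list(self.outside_ids),
        }


def bland_altman(
    first: Sequence[float],
    second: Sequence[float],
    ids: Sequence[str] | None = None,
    variable: str = "value",
    confidence: float = 0.95,
) -> BlandAltmanResults:
    """Compute the Bland–Altman agreement statistics for paired measurements."""
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("first and second must have equal length")
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 pairs, got {n}")
    id_tuple = tuple(str(i) for i in ids) if ids is not None else tuple(str(i) for i in range(n))
    if len(id_tuple) != n:
        raise ParameterError("ids length must match number of pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - LOA_FACTOR * sd_diff
    loa_high = mean_diff + LOA_FACTOR * sd_diff
    half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1)) * sd_diff / np.sqrt(n)
    outside = (d < loa_low) | (d > loa_high)
    return BlandAltmanResults(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_mean_diff=(mean_diff - half, mean_diff + half),
        outside_loa=int(outside.sum()),
        outside_ids=tuple(np.array(id_tuple)[outside]),
        first=x,
        second=y,
        ids=id_tuple,
        variable=variable,
    )


def agreement_plot_data(
    first: Sequence[float], second: Sequence[float]
) -> dict:
    """Convenience wrapper: Bland–Altman plot data without keeping the results."""
    return bland_altman(first, second).plot_data()


class BlandAltman:
    """Agreement model for first vs second measurements of one variable."""

    def __init__(
        self,
        first: Sequence[float],
        second: Sequence[float],
        ids: Sequence[str] | None = None,
        variable: str = "value",
    ):
        self.first = np.asarray(first, dtype=float)
        self.second = np.asarray(second, dtype=float)
        self.ids = ids
        self.variable = variable

    @classmethod
    def from_cohort(cls, table: CohortTable, parameter: str) -> "BlandAltman":
        """Pair repeats 1 and 2 of ``parameter`` (a cohort column such as
        ``pdmax_mv``); subjects without both repeats are excluded."""
        df = table.to_dataframe()
        if parameter not in df.columns:
            raise ParameterError(f"unknown parameter column: {parameter}")
        wide = df.pivot(index="subject_id", columns="repeat_id", values=parameter)
        if 1 not in wide.columns or 2 not in wide.columns:
            raise InsufficientDataError("cohort must contain repeat_id 1 and 2")
        wide = wide[[1, 2]].dropna()
        return cls(
            wide[1].to_numpy(), wide[2].to_numpy(), ids=list(wide.index), variable=parameter
        )

    def fit(self, confidence: float = 0.95) -> BlandAltmanResults:
        return bland_altman(
            self.first, self.second, ids=self.ids, variable=self.variable, confidence=confidence
        )
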