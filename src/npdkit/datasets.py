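"""Published reference values bundled for validation and examples.

``cf_reference_cohort`` returns published NPD results for a reference group
of 11 CF patients: PDmax, Δamil and TCR as printed
(integer mV), together with the Wilschanski index and Sermet score values the
original report prints for each patient.  Recomputing the scores from the
printed integer parameters reproduces the printed scores at two decimals for
patients 2–11; patient 1's printed scores (1.84 / −2.11) were evidently
computed from unrounded source measurements (the printed integers give
1.99 / −2.01), so that row is exempt from exact-reproduction checks.

``group_reference_summaries`` returns the published per-group means and SDs
of the three-arm cohort (11 CF, 19 non-CF, 48 healthy volunteers); these are
also the defaults of the synthetic cohort generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cf_reference_cohort", "group_reference_summaries"]

# patient, pdmax_mv, damil_mv, tcr_mv, wi_published, ss_published
_CF_ROWS = [
    (1, -47, 16, 11, 1.84, -2.11),
    (2, -20, 6, -5, 0.43, 0.25),
    (3, -25, 7, -1, 0.87, -0.24),
    (4, -30, 16, -7, 0.65, -0.03),
    (5, -34, 11, -7, 0.53, 0.22),
    (6, -29, 15, 4, 1.31, -1.19),
    (7, -39, 11, -2, 0.83, -0.33),
    (8, -37, 25, -8, 0.73, -0.37),
    (9, -15, 10, 1, 1.11, -0.61),
    (10, -40, 21, 3, 1.15, -1.38),
    (11, -30, 19, -5, 0.77, -0.40),
]

#: Patients whose printed scores do not derive from the printed integer
#: parameters (unrounded-source rows).
UNROUNDED_SOURCE_PATIENTS = (1,)

# group, n, then (mean, sd) for pdmax, damil, tcr, wi, ss
_GROUP_ROWS = [
    ("CF", 11, -31.7, 9.5, 15.0, 7.2, -1.5, 5.8, 0.9, 0.4, -0.6, 0.7),
    ("non_CF", 19, -16.4, 6.9, 7.5, 4.2, -15.3, 5.7, 0.1, 0.1, 1.3, 0.6),
    ("healthy", 48, -15.2, 7.6, 7.8, 4.7, -13.0, 6.7, 0.2, 0.2, 1.0, 0.7),
]


def cf_reference_cohort() -> pd.DataFrame:
    """Published per-patient NPD results of the 11-patient CF reference group."""
    return pd.DataFrame(
        _CF_ROWS,
        columns=["patient", "pdmax_mv", "damil_mv", "tcr_mv", "wi_published", "ss_published"],
    )


def group_reference_summaries() -> pd.DataFrame:
    """Published group means and SDs (mV for parameters; scores dimensionless)."""
    return pd.DataFrame(
        _GROUP_ROWS,
        columns=[
            "group",
            "n",
            "pdmax_mean",
            "pdmax_sd",
            "damil_mean",
            "damil_sd",
            "tcr_mean",
            "tcr_sd",
            "wi_mean",
            "wi_sd",
            "ss_mean",
            "ss_sd",
        ],
    )
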