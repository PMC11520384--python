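"""Published per-configuration classification scores from the original
soybean/coleus spider-mite study.

The original imagery is not publicly deposited, but the study's two results
tables are: 16 rows per species, one per combination of spatial binning level
(1, 5, 7, 9), session (noon/midnight), and post-infestation period (1 = 7-9
days, 2 = 14-16 days), with per-class accuracies (baseline/control/low/high),
overall 10-fold accuracy K-1 (%), and Cohen's kappa. These printed values are
inputs for the aggregation utilities (session means, ANOVA comparison,
improvement summaries) and for validating them against the study's printed
summary rows.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "soybean_results",
    "coleus_results",
    "PUBLISHED_SUMMARY",
]

_COLUMNS = ["bin_factor", "pixels", "session", "period",
            "base", "control", "low", "high", "k1", "kappa"]

_SOYBEAN_ROWS = [
    (1, 1200, "noon", 1, 0.87, 0.65, 0.62, 0.62, 63.04, 0.59),
    (5, 1200, "noon", 1, 0.97, 0.77, 0.68, 0.70, 75.58, 0.71),
    (7, 600, "noon", 1, 0.98, 0.79, 0.70, 0.70, 75.96, 0.72),
    (9, 375, "noon", 1, 0.98, 0.79, 0.71, 0.78, 76.93, 0.76),
    (1, 1200, "noon", 2, 0.99, 0.69, 0.52, 0.65, 65.79, 0.62),
    (5, 1200, "noon", 2, 1.00, 0.71, 0.61, 0.75, 73.52, 0.69),
    (7, 600, "noon", 2, 1.00, 0.76, 0.58, 0.78, 74.58, 0.71),
    (9, 375, "noon", 2, 1.00, 0.73, 0.69, 0.78, 75.80, 0.73),
    (1, 1200, "midnight", 1, 0.97, 0.71, 0.65, 0.62, 68.56, 0.65),
    (5, 1200, "midnight", 1, 0.99, 0.86, 0.76, 0.77, 82.67, 0.79),
    (7, 600, "midnight", 1, 0.99, 0.85, 0.75, 0.79, 83.46, 0.80),
    (9, 375, "midnight", 1, 0.99, 0.88, 0.78, 0.77, 83.60, 0.81),
    (1, 1200, "midnight", 2, 0.99, 0.75, 0.58, 0.64, 68.67, 0.66),
    (5, 1200, "midnight", 2, 1.00, 0.84, 0.60, 0.74, 77.17, 0.73),
    (7, 600, "midnight", 2, 1.00, 0.86, 0.63, 0.78, 78.58, 0.76),
    (9, 375, "midnight", 2, 1.00, 0.85, 0.57, 0.81, 77.27, 0.74),
]

_COLEUS_ROWS = [
    (1, 1200, "noon", 1, 0.80, 0.60, 0.42, 0.50, 51.83, 0.44),
    (5, 1200, "noon", 1, 0.90, 0.60, 0.47, 0.68, 62.38, 0.55),
    (7, 600, "noon", 1, 0.91, 0.64, 0.54, 0.69, 65.13, 0.59),
    (9, 375, "noon", 1, 0.93, 0.59, 0.55, 0.66, 63.20, 0.58),
    (1, 1200, "noon", 2, 0.89, 0.63, 0.47, 0.59, 57.81, 0.52),
    (5, 1200, "noon", 2, 0.96, 0.62, 0.51, 0.68, 65.98, 0.59),
    (7, 600, "noon", 2, 0.96, 0.63, 0.54, 0.66, 64.83, 0.59),
    (9, 375, "noon", 2, 0.96, 0.66, 0.52, 0.69, 65.73, 0.61),
    (1, 1200, "midnight", 1, 0.77, 0.60, 0.36, 0.58, 51.67, 0.44),
    (5, 1200, "midnight", 1, 0.90, 0.67, 0.49, 0.69, 64.83, 0.58),
    (7, 600, "midnight", 1, 0.91, 0.71, 0.48, 0.73, 65.33, 0.61),
    (9, 375, "midnight", 1, 0.89, 0.71, 0.54, 0.75, 67.13, 0.63),
    (1, 1200, "midnight", 2, 0.88, 0.62, 0.40, 0.58, 55.60, 0.49),
    (5, 1200, "midnight", 2, 0.95, 0.66, 0.51, 0.71, 67.90, 0.62),
    (7, 600, "midnight", 2, 0.95, 0.67, 0.52, 0.74, 66.29, 0.63),
    (9, 375, "midnight", 2, 0.97, 0.69, 0.52, 0.72, 67.13, 0.64),
]

# printed session-mean summary rows of the two published tables
PUBLISHED_SUMMARY = {
    "soybean": {
        "noon": {"base": 0.97, "control": 0.74, "low": 0.64, "high": 0.72,
                 "k1": 72.65, "kappa": 0.69},
        "midnight": {"base": 0.99, "control": 0.82, "low": 0.67, "high": 0.74,
                     "k1": 77.50, "kappa": 0.74},
    },
    "coleus": {
        "noon": {"base": 0.91, "control": 0.62, "low": 0.50, "high": 0.64,
                 "k1": 62.11, "kappa": 0.56},
        "midnight": {"base": 0.90, "control": 0.67, "low": 0.47, "high": 0.69,
                     "k1": 63.24, "kappa": 0.58},
    },
}


def soybean_results() -> pd.DataFrame:
    """The 16 published soybean classification rows."""
    df = pd.DataFrame(_SOYBEAN_ROWS, columns=_COLUMNS)
    df.insert(0, "species", "soybean")
    return df


def coleus_results() -> pd.DataFrame:
    """The 16 published coleus classification rows."""
    df = pd.DataFrame(_COLEUS_ROWS, columns=_COLUMNS)
    df.insert(0, "species", "coleus")
    return df
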