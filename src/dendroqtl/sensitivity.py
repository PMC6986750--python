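"""Per-clone climate-sensitivity traits.

A sensitivity trait is the Pearson correlation between a clone's relative
BAI chronology and one lagged monthly climate variable.  The month window
spans June of the year before ring formation (labels p06..p12) through
September of the ring-formation year (c01..c09) — 16 labels.  The trait
vector over clones for one chosen (variable, threshold, month) cell is the
phenotype handed to QTL mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rings import CloneChronology

__all__ = [
    "MONTH_WINDOW",
    "parse_month_label",
    "align_lagged_series",
    "sensitivity_trait",
    "compute_traits",
    "significance_counts",
    "select_qtl_phenotype",
]

#: Ordered month labels: prior-year June..December, current-year January..September.
MONTH_WINDOW: tuple[str, ...] = tuple(
    [f"p{m:02d}" for m in range(6, 13)] + [f"c{m:02d}" for m in range(1, 10)]
)


def parse_month_label(label: str) -> tuple[int, int]:
    """Return (year lag, calendar month): lag 1 for p-labels, 0 for c-labels."""
    if len(label) != 3 or label[0] not in "pc" or not label[1:].isdigit():
        raise ValueError(f"bad month label {label!r}")
    return (1 if label[0] == "p" else 0), int(label[1:])


def align_lagged_series(
    chronology: CloneChronology, matrix: pd.DataFrame, label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pair relative BAI of ring year Y with the climate value at
    (Y - lag, month); years missing on either side are dropped."""
    if label not in MONTH_WINDOW:
        raise ValueError(f"month label {label!r} outside the analysis window")
    lag, month = parse_month_label(label)
    if month not in matrix.columns:
        raise ValueError(f"month {month} absent from climate matrix")
    clim = matrix[month]
    y_vals, c_vals = [], []
    for year, value in zip(chronology.years, chronology.values):
        key = int(year) - lag
        if key in clim.index:
            cv = clim.loc[key]
            if np.isfinite(value) and np.isfinite(cv):
                y_vals.append(value)
                c_vals.append(float(cv))
    return np.asarray(y_vals), np.asarray(c_vals)


def sensitivity_trait(growth: np.ndarray, clim: np.ndarray) -> tuple[float, float, int]:
    """Pearson r and two-sided t-test p-value (df = n - 2).

    Returns (nan, nan, n) when fewer than 3 complete pairs exist or either
    vector is constant; a missing trait, not an error.
    """
    n = growth.size
    if n < 3 or np.ptp(growth) == 0 or np.ptp(clim) == 0:
        return math.nan, math.nan, n
    r, p = stats.pearsonr(growth, clim)
    return float(r), float(p), n


@dataclass(frozen=True)
class TraitKey:
    variable: str
    threshold: "int | None"
    month_label: str


def compute_traits(
    chronologies: list[CloneChronology],
    matrices: dict[tuple[str, "int | None"], pd.DataFrame],
    window: tuple[str, ...] = MONTH_WINDOW,
) -> pd.DataFrame:
    """Correlation traits for every clone x variable x month-label cell.

    ``matrices`` maps (variable name, threshold or None) to a year x month
    matrix.  Returns a long-format frame with columns clone_id, site,
    variable, threshold, month_label, r, p, n.
    """
    rows = []
    for ch in chronologies:
        for (variable, threshold), matrix in matrices.items():
            for label in window:
                g, c = align_lagged_series(ch, matrix, label)
                r, p, n = sensitivity_trait(g, c)
                rows.append((ch.clone_id, ch.site, variable, threshold, label, r, p, n))
    return pd.DataFrame(
        rows,
        columns=["clone_id", "site", "variable", "threshold", "month_label", "r", "p", "n"],
    )


def significance_counts(traits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Count clones with significant positive / negative correlations.

    One row per (site, variable, threshold, month_label); the bar-chart
    data summarising how many clones respond to each lagged month.
    """
    t = traits.copy()
    t["sig_pos"] = (t["p"] < alpha) & (t["r"] > 0)
    t["sig_neg"] = (t["p"] < alpha) & (t["r"] < 0)
    out = (
        t.groupby(["site", "variable", "threshold", "month_label"], dropna=False)[
            ["sig_pos", "sig_neg"]
        ]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"sig_pos": "n_positive", "sig_neg": "n_negative"})
    )
    return out


def select_qtl_phenotype(
    traits: pd.DataFrame,
    variable: str,
    threshold: "int | None",
    month_label: str,
    min_fraction: float = 0.8,
) -> pd.Series:
    """Extract the per-clone phenotype vector for one trait cell.

    The phenotype is the correlation coefficient itself.  Clones with a
    missing trait are excluded; if the non-missing fraction falls below
    ``min_fraction`` the cell is rejected as too incomplete to map.
    """
    if month_label not in MONTH_WINDOW:
        raise ValueError(f"month label {month_label!r} outside the analysis window")
    if threshold is None:
        mask_thr = traits["threshold"].isna()
    else:
        mask_thr = traits["threshold"] == threshold
    cell = traits[
        (traits["variable"] == variable) & mask_thr & (traits["month_label"] == month_label)
    ]
    if cell.empty:
        raise ValueError(f"no traits for ({variable}, {threshold}, {month_label})")
    y = cell.set_index("clone_id")["r"]
    frac = y.notna().mean()
    if frac < min_fraction:
        raise ValueError(
            f"trait ({variable}, {threshold}, {month_label}) missing for "
            f"{1 - frac:.0%} of clones (limit {1 - min_fraction:.0%})"
        )
    return y.dropna()
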