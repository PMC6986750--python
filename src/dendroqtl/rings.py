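"""Per-tree ring widths -> per-clone relative BAI chronologies.

The processing chain mirrors standard dendrochronological practice for
young clonal trials: ring widths are converted to basal area increments
(BAI), the age/size trend is removed with a modified Hugershoff curve,
serial correlation is removed with an AR(1) prewhitening step, and
replicate trees of a clone are averaged per calendar year with Tukey's
biweight robust mean.  The resulting per-clone index ("relative BAI") is
the growth signal correlated with climate downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RingSeries",
    "BAISeries",
    "HugershoffFit",
    "CloneChronology",
    "bai_from_widths",
    "average_paired_widths",
    "fit_hugershoff",
    "detrend",
    "prewhiten_ar1",
    "tukey_biweight_mean",
    "build_clone_chronology",
    "process_ring_table",
]


@dataclass
class RingSeries:
    """Annual ring widths (mm) of one tree, in year order."""

    tree_id: str
    clone_id: str
    site: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"tree {self.tree_id}: widths must be a non-empty 1-d array")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.widths.size)


@dataclass
class BAISeries:
    """Basal area increments (mm^2/year) of one tree."""

    tree_id: str
    years: np.ndarray
    bai: np.ndarray


@dataclass
class HugershoffFit:
    """Fitted age-trend curve g(t) = A * t^b * exp(-c*t) + d.

    ``fallback`` is set when the nonlinear fit did not converge (or produced
    a non-positive curve) and the horizontal mean was used instead.
    """

    A: float
    b: float
    c: float
    d: float
    converged: bool
    fallback: bool

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * t**self.b * np.exp(-self.c * t) + self.d


@dataclass
class CloneChronology:
    """Per-clone relative BAI index by calendar year."""

    clone_id: str
    site: str
    years: np.ndarray
    values: np.ndarray
    n_reps: np.ndarray = field(default=None)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"))


def bai_from_widths(series: RingSeries) -> BAISeries:
    """Convert cumulative ring widths to basal area increments.

    With cumulative radius r_t = sum of widths up to ring t (r_0 = 0),
    BAI_t = pi * (r_t^2 - r_{t-1}^2).  Total basal area is conserved:
    the BAI values sum to pi * r_T^2.
    """
    w = series.widths
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        bad = int(np.flatnonzero(~(w > 0) | ~np.isfinite(w))[0])
        raise ValueError(
            f"tree {series.tree_id}: non-positive ring width in year "
            f"{series.first_year + bad}"
        )
    r = np.cumsum(w)
    r_prev = np.concatenate([[0.0], r[:-1]])
    bai = np.pi * (r**2 - r_prev**2)
    return BAISeries(tree_id=series.tree_id, years=series.years, bai=bai)


def average_paired_widths(a: RingSeries, b: RingSeries) -> RingSeries:
    """Average the two radial measurement series of one tree element-wise."""
    if a.widths.size != b.widths.size or a.first_year != b.first_year:
        raise ValueError(
            f"tree {a.tree_id}: paired series mismatch "
            f"({a.widths.size} rings from {a.first_year} vs "
            f"{b.widths.size} from {b.first_year})"
        )
    return RingSeries(
        tree_id=a.tree_id,
        clone_id=a.clone_id,
        site=a.site,
        first_year=a.first_year,
        widths=0.5 * (a.widths + b.widths),
    )


def _hugershoff(t, A, b, c, d):
    return A * t**b * np.exp(-c * t) + d


def _mean_fallback(bai: np.ndarray) -> HugershoffFit:
    return HugershoffFit(A=0.0, b=0.0, c=0.0, d=float(np.mean(bai)),
                         converged=False, fallback=True)


def fit_hugershoff(bai: BAISeries) -> HugershoffFit:
    """Fit the modified Hugershoff age-trend curve to a BAI series.

    Ring age t is 1-based from the innermost measured ring.  Initial values
    come from a log-linear regression of log(BAI) on (log t, t); the fit is
    constrained to A > 0 and c >= 0.  On failure, or if the fitted curve is
    not strictly positive over the observed ages (which would break ratio
    detrending), the horizontal mean curve is returned with the fallback
    flag set.
    """
    y = np.asarray(bai.bai, dtype=float)
    if y.size < 4:
        raise ValueError(f"tree {bai.tree_id}: need >= 4 rings to fit 4 parameters, got {y.size}")
    t = np.arange(1, y.size + 1, dtype=float)
    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        # constant series: the mean curve is exact
        return _mean_fallback(y)

    # log-linear initialisation: log y ~ log A + b log t - c t
    with np.errstate(invalid="ignore", divide="ignore"):
        ly = np.log(np.maximum(y, 1e-12))
    Xd = np.column_stack([np.ones_like(t), np.log(t), -t])
    coef, *_ = np.linalg.lstsq(Xd, ly, rcond=None)
    p0 = [max(np.exp(coef[0]), 1e-8), coef[1], max(coef[2], 0.0), 0.0]
    lo = [1e-12, -10.0, 0.0, -np.inf]
    hi = [np.inf, 10.0, 5.0, np.inf]
    p0 = np.clip(p0, lo, hi)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_hugershoff, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        fit = HugershoffFit(*[float(v) for v in popt], converged=True, fallback=False)
    except (RuntimeError, ValueError):
        return _mean_fallback(y)

    if np.any(fit.curve(t) <= 0):
        return _mean_fallback(y)
    return fit


def detrend(bai: BAISeries, fit: HugershoffFit, mode: str = "ratio") -> np.ndarray:
    """Remove the fitted age trend from a BAI series.

    ``ratio`` (default, the ring-width-index convention) divides by the
    fitted curve; ``difference`` subtracts it.
    """
    t = np.arange(1, bai.bai.size + 1, dtype=float)
    g = fit.curve(t)
    if np.any(g <= 0) and mode == "ratio":
        raise ValueError(f"tree {bai.tree_id}: fitted curve not positive; use fallback fit")
    if mode == "ratio":
        return bai.bai / g
    if mode == "difference":
        return bai.bai - g
    raise ValueError(f"unknown detrend mode {mode!r}")


def prewhiten_ar1(x: np.ndarray, keep_first: bool = True) -> tuple[np.ndarray, float]:
    """Remove lag-1 autocorrelation by conditional least squares.

    The series is centred, phi is the OLS slope of x_t on x_{t-1}, and the
    residuals e_t = x_t - phi*x_{t-1} (t >= 2) are returned.  With
    ``keep_first`` the centred first observation is retained as e_1 so the
    residual series keeps the calendar-year alignment of the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 observations for AR(1), got {x.size}")
    xc = x - x.mean()
    denom = float(np.dot(xc[:-1], xc[:-1]))
    if denom <= 1e-300:
        phi = 0.0
    else:
        phi = float(np.dot(xc[1:], xc[:-1]) / denom)
    if abs(phi) >= 1.0:
        warnings.warn(f"AR(1) estimate {phi:.3f} clipped to (-1, 1)", stacklevel=2)
        phi = float(np.clip(phi, -0.999, 0.999))
    resid = xc[1:] - phi * xc[:-1]
    if keep_first:
        resid = np.concatenate([[xc[0]], resid])
    return resid, phi


def tukey_biweight_mean(values, c: float = 9.0, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Tukey's biweight robust location estimate.

    Iterates from the median with MAD scale; points beyond c*MAD get zero
    weight.  c = 9 is the usual tuning constant for tree-ring chronology
    averaging.  If the MAD is zero the current location (median) is returned.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight mean of empty input")
    m = float(np.median(x))
    for _ in range(max_iter):
        s = float(np.median(np.abs(x - m)))
        if s <= 0:
            return m
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() <= 0:
            return m
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def build_clone_chronology(
    residual_series: dict[str, pd.Series], clone_id: str, site: str = ""
) -> CloneChronology:
    """Combine replicate trees of one clone into a per-year biweight mean.

    ``residual_series`` maps tree id -> pandas Series of relative BAI
    indexed by calendar year.  Years are aligned by calendar year; each
    year's value is the biweight mean over the replicates present that year.
    """
    if not residual_series:
        raise ValueError(f"clone {clone_id}: no replicate trees")
    frame = pd.DataFrame(residual_series)
    frame = frame.dropna(how="all")
    if frame.empty:
        raise ValueError(f"clone {clone_id}: replicates share no years")
    years = frame.index.to_numpy(dtype=int)
    vals = np.empty(len(frame))
    n_reps = np.empty(len(frame), dtype=int)
    for i, (_, row) in enumerate(frame.iterrows()):
        v = row.dropna().to_numpy()
        vals[i] = tukey_biweight_mean(v)
        n_reps[i] = v.size
    return CloneChronology(clone_id=clone_id, site=site, years=years,
                           values=vals, n_reps=n_reps)


def process_ring_table(
    rings: pd.DataFrame, detrend_mode: str = "ratio", keep_first: bool = True
) -> list[CloneChronology]:
    """Run the full chain on a long-format ring-width table.

    Expects columns tree_id, clone_id, site, year, width_mm (one row per
    tree x year).  Per tree: widths -> BAI -> Hugershoff detrend -> AR(1)
    prewhitening; per clone: per-year biweight mean across replicates.
    """
    required = {"tree_id", "clone_id", "site", "year", "width_mm"}
    missing = required - set(rings.columns)
    if missing:
        raise ValueError(f"ring table is missing columns: {sorted(missing)}")

    per_clone: dict[tuple[str, str], dict[str, pd.Series]] = {}
    for (tree_id, clone_id, site), grp in rings.groupby(
        ["tree_id", "clone_id", "site"], sort=True
    ):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if not np.all(np.diff(years) == 1):
            raise ValueError(f"tree {tree_id}: ring years not consecutive")
        series = RingSeries(
            tree_id=str(tree_id), clone_id=str(clone_id), site=str(site),
            first_year=int(years[0]), widths=grp["width_mm"].to_numpy(),
        )
        bai = bai_from_widths(series)
        fit = fit_hugershoff(bai)
        index = detrend(bai, fit, mode=detrend_mode)
        resid, _phi = prewhiten_ar1(index, keep_first=keep_first)
        yrs = years if keep_first else years[1:]
        per_clone.setdefault((str(clone_id), str(site)), {})[str(tree_id)] = pd.Series(
            resid, index=yrs
        )

    return [
        build_clone_chronology(trees, clone_id=cid, site=site)
        for (cid, site), trees in sorted(per_clone.items())
    ]


def chronologies_to_frame(chronologies: list[CloneChronology]) -> pd.DataFrame:
    """Long-format table (clone_id, site, year, relative_bai, n_reps)."""
    rows = []
    for ch in chronologies:
        n = ch.n_reps if ch.n_reps is not None else np.ones(len(ch.years), dtype=int)
        for y, v, k in zip(ch.years, ch.values, n):
            rows.append((ch.clone_id, ch.site, int(y), float(v), int(k)))
    return pd.DataFrame(rows, columns=["clone_id", "site", "year", "relative_bai", "n_reps"])
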