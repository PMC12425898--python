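"""Site chronologies and common-signal statistics.

Per-tree sector series are z-transformed over a common period and averaged
across trees into site chronologies; ring-width series are variance-
stabilized by a spread-vs-level power transform, detrended with a cubic
smoothing spline whose frequency response is 50% at a wavelength of 66% of
the series length, and averaged with the Tukey biweight robust mean.

Chronology quality is summarised by the classical dendrochronology
statistics: the mean interseries correlation r̄ (Rbar), the expressed
population signal EPS = n·r̄ / (n·r̄ + 1 − r̄), the signal-to-noise ratio
SNR = n·r̄ / (1 − r̄) (so EPS = SNR/(1+SNR)), and the lag-1 autocorrelation.
A two-group one-way ANOVA (:func:`split_group_test`) tests for a level
shift around a changepoint year.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import xarray as xr
from scipy import interpolate, stats

from .io_formats import RingWidthSet, ValidationError
from .tracheidogram import sector_labels

logger = logging.getLogger(__name__)

__all__ = [
    "SectorChronology",
    "ChronologyStats",
    "RWIndexSeries",
    "ztransform",
    "first_difference",
    "biweight_mean",
    "power_transform",
    "spline_detrend",
    "detrend_ringwidths",
    "rw_chronology",
    "rbar",
    "interseries_correlations",
    "eps",
    "snr",
    "ar1",
    "sector_chronology",
    "chronology_frame",
    "chronology_stats",
    "split_group_test",
]


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------


def _as_series(x) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    x = np.asarray(x, dtype=float)
    return pd.Series(x, index=np.arange(len(x)))


def ztransform(series, period: tuple[int, int] | None = None) -> pd.Series:
    """Standardize a series to mean 0, SD 1 (sample SD, n−1).

    The mean and SD are computed over ``period`` (an inclusive year span on
    the series index; default: all years); values outside the period are
    scaled with the same constants. Raises on constant series or fewer than
    3 in-period values.
    """
    s = _as_series(series)
    sel = s if period is None else s.loc[(s.index >= period[0]) & (s.index <= period[1])]
    sel = sel.dropna()
    if len(sel) < 3:
        raise ValidationError("need at least 3 non-missing values to z-transform")
    mu = sel.mean()
    sd = sel.std(ddof=1)
    if not sd > 0:
        raise ValidationError("cannot z-transform a constant series")
    return (s - mu) / sd


def first_difference(series) -> pd.Series:
    """Year-to-year changes d_t = x_{t+1} − x_t, labelled by the later year.

    First differencing is the high-pass filter used to strip shared
    low-frequency variance before correlation analysis.
    """
    s = _as_series(series)
    if len(s) < 2:
        raise ValidationError("need at least 2 values to difference")
    return s.diff().iloc[1:]


def biweight_mean(
    values, c: float = 9.0, tol: float = 1e-6, max_iter: int = 100
) -> float:
    """Tukey biweight robust location.

    Iterates the weighted mean with weights w = (1 − u²)² for |u| < 1 (else
    0), u = (x − T)/(c·MAD), starting from the median, until successive
    estimates move less than ``tol``. With the conventional c = 9 the
    estimator discounts values beyond ~6 sigma entirely while matching the
    arithmetic mean on clean symmetric data. If the MAD is zero (at least
    half the values identical) the median is returned directly.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("biweight mean of no finite values")
    if not c > 0:
        raise ValidationError("tuning constant c must be positive")
    t = np.median(x)
    mad = np.median(np.abs(x - t))
    if mad == 0:
        return float(t)
    for _ in range(max_iter):
        u = (x - t) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        t_new = np.sum(w * x) / np.sum(w)
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


# ---------------------------------------------------------------------------
# ring-width standardization
# ---------------------------------------------------------------------------


class PowerTransformResult(NamedTuple):
    values: pd.Series
    power: float
    slope: float


def power_transform(widths) -> PowerTransformResult:
    """Variance-stabilizing power transform for ring widths.

    Regresses log local spread ``|x_t − x_{t−1}|`` on log local mean
    ``(x_t + x_{t−1})/2``; the optimal power is p = 1 − slope, clamped to
    [−1, 1]. The series is returned in the Box–Cox form (x**p − 1)/p —
    monotone increasing for every p, so the transform can never invert the
    growth signal — or log(x) when |p| < 0.05 (the Box–Cox limit).
    Homogeneous series (slope ≈ 0) are left nearly unchanged up to a unit
    shift; spread proportional to level (slope ≈ 1) maps to logs.
    """
    s = _as_series(widths).dropna()
    if len(s) < 10:
        raise ValidationError("need at least 10 widths for a power transform")
    if not (s > 0).all():
        raise ValidationError("power transform requires strictly positive widths")
    x = s.to_numpy()
    spread = np.abs(np.diff(x))
    level = (x[1:] + x[:-1]) / 2.0
    ok = spread > 0
    if ok.sum() < 3:
        raise ValidationError("too few positive-spread pairs for the regression")
    slope, _ = np.polyfit(np.log(level[ok]), np.log(spread[ok]), 1)
    p = float(np.clip(1.0 - slope, -1.0, 1.0))
    if abs(p) < 0.05:
        out = pd.Series(np.log(s.to_numpy()), index=s.index)
        p_eff = 0.0
    else:
        out = pd.Series((s.to_numpy() ** p - 1.0) / p, index=s.index)
        p_eff = p
    return PowerTransformResult(values=out, power=p_eff, slope=float(slope))


@dataclass
class RWIndexSeries:
    """Detrended ring-width indices (raw/fit, mean ≈ 1) with the fit curve."""

    core_id: str | None
    years: np.ndarray
    index: pd.Series
    fit: pd.Series


def _spline_lambda(n: int, stiffness_frac: float, cutoff_amplitude: float) -> float:
    """Smoothing penalty giving frequency response ``cutoff_amplitude`` at
    wavelength ``stiffness_frac · n`` samples.

    The cubic smoothing spline minimises Σ(y−f)² + λ∫f″², whose response to
    a sinusoid of angular frequency ω (rad/sample) is 1/(1 + λω⁴); solving
    for amplitude A at ω = 2π/wavelength gives λ = (1−A)/A · (wl/2π)⁴.
    """
    wavelength = stiffness_frac * n
    a = cutoff_amplitude
    return (1.0 - a) / a * (wavelength / (2.0 * np.pi)) ** 4


def spline_detrend(
    series,
    stiffness_frac: float = 0.66,
    cutoff_amplitude: float = 0.5,
    core_id: str | None = None,
) -> RWIndexSeries:
    """Detrend a ring-width series with a cubic smoothing spline.

    The spline's stiffness is set so that its frequency-response amplitude
    equals ``cutoff_amplitude`` (default 50%) at a wavelength of
    ``stiffness_frac`` (default 66%) of the series length — variance at
    longer wavelengths (age/size trends) is mostly absorbed by the fit,
    shorter (climatic) wavelengths mostly survive in the index. Each year's
    value is divided by the fitted curve, yielding a dimensionless index
    with mean ≈ 1.
    """
    s = _as_series(series).dropna()
    n = len(s)
    if n < 10:
        raise ValidationError("need at least 10 values to detrend")
    if not 0 < stiffness_frac <= 1:
        raise ValidationError("stiffness_frac must be in (0, 1]")
    lam = _spline_lambda(n, stiffness_frac, cutoff_amplitude)
    x = np.arange(n, dtype=float)
    spl = interpolate.make_smoothing_spline(x, s.to_numpy(), lam=lam)
    fit = spl(x)
    if np.any(fit <= 0):
        raise ValidationError(
            "spline fit is non-positive; power-transform the series first"
        )
    idx = pd.Series(s.to_numpy() / fit, index=s.index)
    return RWIndexSeries(
        core_id=core_id,
        years=np.asarray(s.index),
        index=idx,
        fit=pd.Series(fit, index=s.index),
    )


def detrend_ringwidths(
    rws: RingWidthSet,
    stiffness_frac: float = 0.66,
    cutoff_amplitude: float = 0.5,
    use_power_transform: bool = True,
) -> dict[str, RWIndexSeries]:
    """Power-transform (optionally) and spline-detrend every core."""
    out = {}
    for cid, (first, w) in rws.series.items():
        s = pd.Series(w, index=np.arange(first, first + len(w)))
        s = s[s > 0]
        if len(s) < 10:
            logger.warning("core %s too short to detrend (%d years)", cid, len(s))
            continue
        if use_power_transform:
            s = power_transform(s).values
            if (s <= 0).any():  # log-transformed series can cross zero
                s = s - s.min() + s.std(ddof=1)
        out[cid] = spline_detrend(
            s, stiffness_frac, cutoff_amplitude, core_id=cid
        )
    if not out:
        raise ValidationError("no core long enough to detrend")
    return out


def rw_chronology(
    indices: dict[str, RWIndexSeries], method: str = "biweight"
) -> "SectorChronology":
    """Average detrended core indices into a site ring-width chronology.

    The biweight robust mean is the default for ring widths because it
    discounts outlier cores year by year.
    """
    frame = pd.DataFrame({cid: r.index for cid, r in indices.items()})
    frame = frame.sort_index()
    years = frame.index.to_numpy()
    vals = np.full(len(years), np.nan)
    depth = frame.notna().sum(axis=1).to_numpy()
    for i, (_, row) in enumerate(frame.iterrows()):
        v = row.dropna().to_numpy()
        if v.size == 0:
            continue
        vals[i] = biweight_mean(v) if method == "biweight" else float(np.mean(v))
    keep = depth > 0
    return SectorChronology(
        sector="RW",
        years=years[keep],
        index=vals[keep],
        depth=depth[keep].astype(float),
        method=method,
    )


# ---------------------------------------------------------------------------
# common-signal statistics
# ---------------------------------------------------------------------------


def interseries_correlations(
    frame: pd.DataFrame,
    period: tuple[int, int] | None = None,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between series (columns of ``frame``).

    Pairs are correlated over their pairwise-complete years within
    ``period``; pairs with fewer than ``min_overlap`` common years are
    excluded with a warning. Returns columns (a, b, r, n).
    """
    df = frame.copy()
    if period is not None:
        df = df.loc[(df.index >= period[0]) & (df.index <= period[1])]
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValidationError("need at least 2 series for interseries correlations")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        pair = df[[a, b]].dropna()
        if len(pair) < min_overlap:
            warnings.warn(
                f"pair ({a}, {b}) excluded: only {len(pair)} overlapping years",
                stacklevel=2,
            )
            continue
        r = float(np.corrcoef(pair[a], pair[b])[0, 1])
        rows.append((a, b, r, len(pair)))
    if not rows:
        raise ValidationError("no series pair has sufficient overlap")
    return pd.DataFrame(rows, columns=["a", "b", "r", "n"])


def rbar(
    frame: pd.DataFrame,
    period: tuple[int, int] | None = None,
    min_overlap: int = 10,
) -> float:
    """Mean interseries correlation r̄ over all usable pairs."""
    return float(interseries_correlations(frame, period, min_overlap)["r"].mean())


def eps(rbar_value: float, n_trees: int) -> float:
    """Expressed population signal: EPS = n·r̄ / (n·r̄ + 1 − r̄).

    Quantifies how well the finite-sample mean chronology tracks the
    hypothetical infinite-population chronology; 1 means perfect agreement.
    """
    if n_trees < 2:
        raise ValidationError("EPS requires at least 2 trees")
    if not -1 < rbar_value <= 1:
        raise ValidationError("rbar must lie in (-1, 1]")
    denom = n_trees * rbar_value + (1.0 - rbar_value)
    if denom <= 0:
        raise ValidationError("EPS undefined for strongly negative rbar")
    return float(n_trees * rbar_value / denom)


def snr(rbar_value: float, n_trees: int) -> float:
    """Signal-to-noise ratio SNR = n·r̄ / (1 − r̄); EPS = SNR/(1+SNR)."""
    if n_trees < 2:
        raise ValidationError("SNR requires at least 2 trees")
    if rbar_value >= 1:
        raise ValidationError("SNR is infinite at rbar = 1")
    if rbar_value <= -1:
        raise ValidationError("rbar must lie in (-1, 1)")
    return float(n_trees * rbar_value / (1.0 - rbar_value))


def ar1(series) -> float:
    """Lag-1 autocorrelation: Pearson r of (x_1..x_{n−1}) with (x_2..x_n)."""
    s = _as_series(series).dropna().to_numpy()
    if len(s) < 10:
        raise ValidationError("need at least 10 values for ar1")
    if np.std(s) == 0:
        raise ValidationError("ar1 of a constant series is undefined")
    return float(np.corrcoef(s[:-1], s[1:])[0, 1])


# ---------------------------------------------------------------------------
# site chronologies
# ---------------------------------------------------------------------------


@dataclass
class SectorChronology:
    """Site-level annual index series for one sector (or ring width)."""

    sector: str
    years: np.ndarray
    index: np.ndarray
    depth: np.ndarray
    method: str = "arithmetic"

    def as_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name=self.sector)


def _tree_frame(matrix: xr.Dataset, param: str, sector: int) -> pd.DataFrame:
    """Year × tree frame of raw sector values from a sector matrix."""
    da = matrix[param].sel(sector=sector)
    return pd.DataFrame(
        da.values.T, index=matrix["year"].values, columns=matrix["tree"].values
    )


def sector_chronology(
    matrix: xr.Dataset,
    param: str = "ld",
    method: str = "arithmetic",
    period: tuple[int, int] | None = None,
) -> dict[str, SectorChronology]:
    """Build one site chronology per sector from a tree × year × sector matrix.

    Each tree's sector series is z-transformed over the common ``period``,
    then the trees are averaged per year (arithmetic mean by default,
    biweight optional). Years with no tree present are reported missing,
    never zero. Returns a mapping sector label → :class:`SectorChronology`.
    """
    if method not in ("arithmetic", "biweight"):
        raise ValidationError(f"unknown chronology method {method!r}")
    labels = matrix.attrs.get(
        "sector_labels", sector_labels(matrix.sizes["sector"])
    )
    out: dict[str, SectorChronology] = {}
    for s_ix, lab in zip(matrix["sector"].values, labels):
        frame = _tree_frame(matrix, param, s_ix)
        if period is not None:
            frame = frame.loc[(frame.index >= period[0]) & (frame.index <= period[1])]
        usable = [c for c in frame.columns if frame[c].notna().sum() >= 3]
        if len(usable) < 2:
            raise ValidationError(f"sector {lab}: fewer than 2 trees with data")
        z = pd.DataFrame({c: ztransform(frame[c]) for c in usable})
        depth = z.notna().sum(axis=1).to_numpy()
        if method == "arithmetic":
            vals = z.mean(axis=1, skipna=True).to_numpy()
        else:
            vals = np.array(
                [
                    biweight_mean(row.dropna()) if row.notna().any() else np.nan
                    for _, row in z.iterrows()
                ]
            )
        keep = depth > 0
        out[lab] = SectorChronology(
            sector=lab,
            years=z.index.to_numpy()[keep],
            index=vals[keep],
            depth=depth[keep].astype(float),
            method=method,
        )
    return out


def chronology_frame(chrons: dict[str, SectorChronology]) -> pd.DataFrame:
    """Year × sector DataFrame of chronology indices."""
    return pd.DataFrame({lab: c.as_series() for lab, c in chrons.items()})


@dataclass
class ChronologyStats:
    """Per-sector descriptive and common-signal statistics."""

    table: pd.DataFrame  # rows: sector labels + "Mean"


def chronology_stats(
    matrix: xr.Dataset,
    param: str = "ld",
    period: tuple[int, int] | None = None,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Descriptive statistics per sector, plus a cross-sector Mean row.

    Columns: ``mean`` and ``sd`` of the raw values (µm; mean over all
    tree×year values, SD of the per-year site-mean series), ``ar1`` of the
    arithmetic mean chronology, ``rbar`` (pairwise, on z-transformed tree
    series), ``eps`` and ``snr`` derived from rbar and the tree count, and
    ``n_trees``. The Mean row is the arithmetic mean of the per-sector
    entries.
    """
    labels = matrix.attrs.get(
        "sector_labels", sector_labels(matrix.sizes["sector"])
    )
    chrons = sector_chronology(matrix, param=param, period=period)
    rows = []
    for s_ix, lab in zip(matrix["sector"].values, labels):
        frame = _tree_frame(matrix, param, s_ix)
        if period is not None:
            frame = frame.loc[(frame.index >= period[0]) & (frame.index <= period[1])]
        n_trees = int(sum(frame[c].notna().sum() >= 3 for c in frame.columns))
        z = pd.DataFrame(
            {c: ztransform(frame[c]) for c in frame.columns if frame[c].notna().sum() >= 3}
        )
        rb = rbar(z, min_overlap=min_overlap)
        rows.append(
            {
                "sector": lab,
                "mean": float(np.nanmean(frame.to_numpy())),
                "sd": float(frame.mean(axis=1, skipna=True).std(ddof=1)),
                "ar1": ar1(chrons[lab].as_series()),
                "rbar": rb,
                "eps": eps(rb, n_trees),
                "snr": snr(rb, n_trees),
                "n_trees": n_trees,
            }
        )
    table = pd.DataFrame(rows).set_index("sector")
    table.loc["Mean"] = table.mean(axis=0)
    return table


# ---------------------------------------------------------------------------
# changepoint group comparison
# ---------------------------------------------------------------------------


@dataclass
class SplitGroupResult:
    """One-way ANOVA comparing years before vs from the split year on."""

    f_stat: float
    p_value: float
    mean_before: float
    mean_after: float
    n_before: int
    n_after: int


def split_group_test(series, split_year: int) -> SplitGroupResult:
    """Two-group fixed-effects ANOVA around a changepoint year.

    Group 1 holds years strictly before ``split_year``; group 2 holds
    ``split_year`` onwards. Equivalent to a pooled-variance two-sample
    t-test (F = t²).
    """
    s = _as_series(series).dropna()
    g1 = s[s.index < split_year].to_numpy()
    g2 = s[s.index >= split_year].to_numpy()
    if len(g1) < 3 or len(g2) < 3:
        raise ValidationError("each group needs at least 3 years")
    if np.std(g1) == 0 and np.std(g2) == 0 and np.mean(g1) == np.mean(g2):
        return SplitGroupResult(0.0, 1.0, float(np.mean(g1)), float(np.mean(g2)),
                                len(g1), len(g2))
    f, p = stats.f_oneway(g1, g2)
    return SplitGroupResult(
        f_stat=float(f),
        p_value=float(p),
        mean_before=float(np.mean(g1)),
        mean_after=float(np.mean(g2)),
        n_before=len(g1),
        n_after=len(g2),
    )
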