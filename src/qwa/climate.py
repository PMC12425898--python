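"""Monthly, seasonal-window, and spatial climate correlations.

The analysis relates annual tree-ring chronologies to monthly climate on a
24-slot month axis running from January of the *previous* year (slot 1,
``pJan``) to December of the *current* growth year (slot 24, ``Dec``). The
default analysis window spans previous-year March through current-year
October (20 slots), the physiologically plausible span for Mediterranean
conifers whose ring partly integrates the prior season.

Three levels of analysis:

* :func:`monthly_correlations` — Pearson r per (chronology, month slot);
* :func:`seasonal_scan` — r for every aggregate window of 1..19 months
  ending in each slot (mean for temperature/drought index, sum for
  precipitation), with :func:`best_season` picking the |r|-optimal window;
* :func:`spatial_correlation` — r between one chronology and every cell of
  a gridded climate field over a fixed seasonal window.

Significance is the exact two-tailed t-transform of r on pairwise-complete
years; no multiple-testing adjustment is applied by default (a
Benjamini–Hochberg flag is available for reanalysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from scipy import stats

from .io_formats import ClimateTable, GridField, ValidationError

__all__ = [
    "SLOT_LABELS",
    "DEFAULT_WINDOW",
    "SeasonWindow",
    "slot_label",
    "label_slot",
    "align_climate",
    "monthly_correlations",
    "seasonal_scan",
    "best_season",
    "critical_r",
    "spatial_correlation",
]

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

#: 24 month slots: previous-year January (pJan) .. current-year December (Dec)
SLOT_LABELS = ["p" + m for m in _MONTHS] + _MONTHS

#: default analysis window, previous-March .. current-October (20 slots)
DEFAULT_WINDOW = (3, 22)


def slot_label(slot: int) -> str:
    if not 1 <= slot <= 24:
        raise ValidationError(f"month slot {slot} outside 1..24")
    return SLOT_LABELS[slot - 1]


def label_slot(label: str) -> int:
    try:
        return SLOT_LABELS.index(label) + 1
    except ValueError as exc:
        raise ValidationError(f"unknown month-slot label {label!r}") from exc


@dataclass(frozen=True)
class SeasonWindow:
    """An aggregate window of ``length`` months ending at ``end_slot``."""

    end_slot: int
    length: int
    aggregate: str = "mean"  # "mean" or "sum"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("window length must be ≥ 1")
        if not 1 <= self.end_slot <= 24:
            raise ValidationError("end slot outside the 24-slot month axis")
        if self.end_slot - self.length + 1 < 1:
            raise ValidationError("window extends before previous-year January")

    @property
    def label(self) -> str:
        start = self.end_slot - self.length + 1
        if self.length == 1:
            return slot_label(self.end_slot)
        return f"{slot_label(start)}-{slot_label(self.end_slot)}"


def default_aggregate(variable: str) -> str:
    """Sum for precipitation (totals are the physical quantity), mean else."""
    return "sum" if "prec" in variable.lower() else "mean"


# ---------------------------------------------------------------------------
# alignment and the core correlation kernel
# ---------------------------------------------------------------------------


def align_climate(climate: ClimateTable, years) -> pd.DataFrame:
    """Arrange climate as a growth-year × 24-slot matrix.

    The row for growth year t holds the calendar months of t−1 in slots
    1–12 and of t in slots 13–24; months outside the climate record stay
    missing.
    """
    years = np.asarray(years, dtype=int)
    if len(years) == 0 or years.max() < climate.years.min() or years.min() - 1 > climate.years.max():
        raise ValidationError("chronology years do not overlap the climate record")
    out = np.full((len(years), 24), np.nan)
    lookup = {int(y): i for i, y in enumerate(climate.years)}
    for i, t in enumerate(years):
        if t - 1 in lookup:
            out[i, :12] = climate.values[lookup[t - 1]]
        if t in lookup:
            out[i, 12:] = climate.values[lookup[t]]
    return pd.DataFrame(out, index=years, columns=np.arange(1, 25))


def _pearson(x: np.ndarray, y: np.ndarray, min_n: int = 10):
    """Pearson r and exact two-tailed p on pairwise-complete observations."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < min_n:
        return np.nan, np.nan, n
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def _maybe_diff(x: np.ndarray) -> np.ndarray:
    """First-difference an annual series, keeping alignment by padding NaN."""
    out = np.full_like(x, np.nan, dtype=float)
    out[1:] = np.diff(x)
    return out


# ---------------------------------------------------------------------------
# monthly correlations
# ---------------------------------------------------------------------------


def monthly_correlations(
    chrons,
    climates: dict[str, ClimateTable],
    alpha: float = 0.05,
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_n: int = 10,
    filter: str = "none",
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson r between chronologies and every monthly climate slot.

    Parameters
    ----------
    chrons
        A year-indexed Series (one chronology) or DataFrame (one column per
        chronology).
    climates
        Mapping variable name → :class:`ClimateTable`.
    filter
        ``"none"`` correlates the raw series; ``"first_diff"`` first-
        differences both the chronology and each monthly series, keeping
        only high-frequency covariance.
    fdr
        Apply Benjamini–Hochberg adjustment to the p-values within each
        (chronology, variable) before the significance mask.

    Returns a tidy DataFrame (chronology, variable, slot, label, r, p, n,
    significant).
    """
    if isinstance(chrons, pd.Series):
        chrons = chrons.to_frame(name=chrons.name or "chron")
    if filter not in ("none", "first_diff"):
        raise ValidationError(f"unknown filter mode {filter!r}")
    slots = list(range(window[0], window[1] + 1))
    rows = []
    for var, ct in climates.items():
        aligned = align_climate(ct, chrons.index)
        for cname in chrons.columns:
            x = chrons[cname].to_numpy(dtype=float)
            if filter == "first_diff":
                x = _maybe_diff(x)
            block = []
            for slot in slots:
                y = aligned[slot].to_numpy()
                if filter == "first_diff":
                    y = _maybe_diff(y)
                r, p, n = _pearson(x, y, min_n=min_n)
                block.append(
                    {
                        "chronology": cname,
                        "variable": var,
                        "slot": slot,
                        "label": slot_label(slot),
                        "r": r,
                        "p": p,
                        "n": n,
                    }
                )
            if fdr:
                _apply_bh(block)
            rows.extend(block)
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] <= alpha
    return df


def _apply_bh(block: list[dict]) -> None:
    from statsmodels.stats.multitest import multipletests

    ps = np.array([b["p"] for b in block])
    ok = np.isfinite(ps)
    if ok.sum() == 0:
        return
    adj = np.full_like(ps, np.nan)
    adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for b, q in zip(block, adj):
        b["p"] = q


# ---------------------------------------------------------------------------
# seasonal-window scan
# ---------------------------------------------------------------------------


def seasonal_scan(
    chron: pd.Series,
    climate: ClimateTable,
    lengths=range(1, 20),
    aggregate: str | None = None,
    alpha: float = 0.05,
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_n: int = 10,
    filter: str = "none",
) -> pd.DataFrame:
    """Correlate a chronology with every aggregate season of 1..19 months.

    For each end slot in the analysis window and each length L, the L
    months ending there are aggregated (mean for temperature/drought
    indices, sum for precipitation — chosen from the variable name when
    ``aggregate`` is None) and correlated with the chronology. Windows that
    would extend before previous-year January, or rows with any missing
    month, are reported missing. The L = 1 row reproduces
    :func:`monthly_correlations` exactly.
    """
    if filter not in ("none", "first_diff"):
        raise ValidationError(f"unknown filter mode {filter!r}")
    agg = aggregate or default_aggregate(climate.variable)
    if agg not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregate {agg!r}")
    aligned = align_climate(climate, chron.index).to_numpy()
    x0 = chron.to_numpy(dtype=float)
    if filter == "first_diff":
        x0 = _maybe_diff(x0)
    rows = []
    for L in lengths:
        for end in range(window[0], window[1] + 1):
            start = end - L + 1
            if start < 1:
                rows.append(
                    {
                        "end_slot": end,
                        "length": L,
                        "label": None,
                        "r": np.nan,
                        "p": np.nan,
                        "n": 0,
                    }
                )
                continue
            cols = aligned[:, start - 1 : end]
            if L == 1:
                y = cols[:, 0]
            else:
                y = cols.sum(axis=1) if agg == "sum" else cols.mean(axis=1)
                y = np.where(np.isnan(cols).any(axis=1), np.nan, y)
            if filter == "first_diff":
                y = _maybe_diff(y)
            r, p, n = _pearson(x0, y, min_n=min_n)
            rows.append(
                {
                    "end_slot": end,
                    "length": L,
                    "label": SeasonWindow(end, L, agg).label,
                    "r": r,
                    "p": p,
                    "n": n,
                }
            )
    df = pd.DataFrame(rows)
    df["variable"] = climate.variable
    df["aggregate"] = agg
    df["significant"] = df["p"] <= alpha
    return df


def best_season(scan: pd.DataFrame) -> pd.Series:
    """The |r|-maximal window of a seasonal scan.

    Ties are broken in favour of the shorter window, then the later end
    month; the sign of r is retained.
    """
    ok = scan.dropna(subset=["r"])
    if ok.empty:
        raise ValidationError("seasonal scan contains no usable windows")
    ranked = ok.assign(_absr=ok["r"].abs()).sort_values(
        ["_absr", "length", "end_slot"],
        ascending=[False, True, False],
        kind="mergesort",
    )
    return ranked.iloc[0].drop("_absr")


def critical_r(n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Pearson-r significance threshold from the exact t transform.

    r* = sqrt(t*² / (t*² + n − 2)) with t* the Student-t critical value at
    ``alpha`` (``tails``-tailed), df = n − 2. Decreases monotonically in n
    and vanishes as alpha → 1.
    """
    if n < 4:
        raise ValidationError("need n ≥ 4 for a critical r")
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    t_crit = stats.t.ppf(1.0 - alpha / tails, n - 2)
    return float(np.sqrt(t_crit**2 / (t_crit**2 + n - 2)))


# ---------------------------------------------------------------------------
# spatial field correlation
# ---------------------------------------------------------------------------


def spatial_correlation(
    chron: pd.Series,
    grid: GridField,
    window: SeasonWindow,
    alpha: float = 0.05,
    min_n: int = 10,
) -> xr.Dataset:
    """Correlation field between a chronology and a gridded climate window.

    For every grid cell the ``window`` months are aggregated per growth
    year and correlated with the chronology; the result carries r, the
    two-tailed p, the per-cell n, and the p ≤ alpha mask.
    """
    if grid.values.size == 0:
        raise ValidationError("empty climate grid")
    years = np.asarray(chron.index, dtype=int)
    start = window.end_slot - window.length + 1
    lookup = {int(y): i for i, y in enumerate(grid.years)}
    nlat, nlon = len(grid.lats), len(grid.lons)
    agg = np.full((len(years), nlat, nlon), np.nan)
    for i, t in enumerate(years):
        parts = []
        complete = True
        for slot in range(start, window.end_slot + 1):
            cal_year = t - 1 if slot <= 12 else t
            month = slot if slot <= 12 else slot - 12
            if cal_year not in lookup:
                complete = False
                break
            parts.append(grid.values[lookup[cal_year], month - 1])
        if not complete:
            continue
        stackd = np.stack(parts)  # (L, nlat, nlon)
        vals = stackd.sum(axis=0) if window.aggregate == "sum" else stackd.mean(axis=0)
        vals = np.where(np.isnan(stackd).any(axis=0), np.nan, vals)
        agg[i] = vals

    x = chron.to_numpy(dtype=float)
    r = np.full((nlat, nlon), np.nan)
    p = np.full((nlat, nlon), np.nan)
    n = np.zeros((nlat, nlon), dtype=int)
    for a in range(nlat):
        for b in range(nlon):
            r[a, b], p[a, b], n[a, b] = _pearson(x, agg[:, a, b], min_n=min_n)
    return xr.Dataset(
        {
            "r": (("lat", "lon"), r),
            "p": (("lat", "lon"), p),
            "n": (("lat", "lon"), n),
            "significant": (("lat", "lon"), p <= alpha),
        },
        coords={"lat": grid.lats, "lon": grid.lons},
        attrs={
            "variable": grid.variable,
            "window": window.label,
            "aggregate": window.aggregate,
            "alpha": alpha,
        },
    )
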