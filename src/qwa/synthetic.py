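"""Synthetic site climate, cell anatomy, and ring widths for pipeline testing.

The study system is a semi-arid mountain juniper stand (six trees, rings
1963–2019) whose tracheid lumen diameter (LD) responds positively to May
precipitation and negatively to growing-season maximum temperature, with a
warming/drying regime shift in the early 1990s. No field data are bundled
with the package, so this module generates data with the same *statistical*
structure — seasonal climatology, AR(1) temperature anomalies, gamma
precipitation with dry summers, a post-break warming trend, multiplicative
log-scale climate effects on sector-level anatomy, weak common signal in
cell wall thickness (CWT), and a negative-exponential age trend in ring
widths. It is explicitly not a xylogenesis model: cells are drawn around
per-sector targets, not grown.

All outputs are bit-reproducible given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ClimateTable, GridField, RingWidthSet, ValidationError

__all__ = ["SyntheticParams", "gen_climate", "gen_climate_grid",
           "gen_anatomy", "gen_ringwidths"]

#: Mediterranean-mountain monthly mean of daily-max temperature, °C
TMAX_CLIMATOLOGY = np.array(
    [8.6, 9.4, 12.8, 17.2, 22.4, 27.1, 30.2, 30.0, 26.6, 21.0, 15.1, 10.3]
)
#: monthly precipitation means with the dry-summer shape, mm
PRECIP_CLIMATOLOGY = np.array(
    [118.0, 98.0, 77.0, 49.0, 28.0, 9.0, 3.0, 4.0, 14.0, 57.0, 95.0, 126.0]
)


@dataclass
class SyntheticParams:
    """Generator conditions.

    The defaults encode the study conditions: 6 trees over 1963–2019 with
    10–14 radial files per ring and ~40 cells per file; base per-sector LD
    means declining 22.4 → 3.7 µm and CWT rising 3.1 → 5.2 µm from ring
    start to end; log-scale (per-SD) climate effects on LD of +0.06 for May
    precipitation and −0.08 for Apr–Oct maximum temperature; a +0.5
    °C/decade Tmax trend beginning at the 1992 break year. CWT carries a
    deliberately weak common signal (betas scaled by ``cwt_beta_scale``
    against larger idiosyncratic noise) so the LD-vs-CWT contrast in
    chronology statistics is reproduced.
    """

    start_year: int = 1963
    end_year: int = 2019
    n_trees: int = 6
    files_per_ring: tuple[int, int] = (10, 14)
    cells_per_file: float = 40.0
    base_ld_profile: tuple = (22.4, 19.7, 18.3, 17.3, 16.3, 15.3, 14.3, 12.9, 10.5, 3.7)
    base_cwt_profile: tuple = (3.1, 3.5, 3.7, 3.9, 4.0, 4.1, 4.3, 4.4, 4.7, 5.2)
    beta_precip_may: float = 0.06
    beta_tmax_summer: float = -0.08
    cwt_beta_scale: float = 0.15
    trend_break_year: int = 1992
    tmax_trend: float = 0.5           # °C per decade after the break
    ld_break_step_sd: float = -0.8    # LD level step at the break, in units of
                                      # the tree-year log-scale SD
    tmax_anom_sd: float = 1.0         # marginal SD of monthly Tmax anomalies, °C
    tmax_anom_ar1: float = 0.5
    precip_gamma_shape: float = 3.0
    spei_tmax_weight: float = 0.5     # drought index: z(precip) − w·z(tmax)
    tree_effect_sd: float = 0.05      # log-scale between-tree level spread
    noise_sd: float = 0.12            # log-scale idiosyncratic tree×year×sector
    cwt_noise_sd: float = 0.10
    cell_noise_sd: float = 0.15       # log-scale cell-to-cell within a file
    cwt_cell_noise_sd: float = 0.10
    drought_cell_sensitivity: float = 0.15  # cells/file shrink in dry years
    n_cores_rw: int = 12
    rw_beta_precip: float = 0.25
    rw_noise_sd: float = 0.15
    seed: int = 42

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValidationError("end_year must exceed start_year")
        if min(self.base_ld_profile) <= 0 or min(self.base_cwt_profile) <= 0:
            raise ValidationError("base profiles must be strictly positive")
        for name in ("tree_effect_sd", "noise_sd", "cell_noise_sd", "rw_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def n_sectors(self) -> int:
        return len(self.base_ld_profile)


def _month_z(values: np.ndarray) -> np.ndarray:
    """Column-wise (per calendar month) z-scores of a year × 12 matrix."""
    mu = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    return (values - mu) / sd


def gen_climate(params: SyntheticParams, seed: int | None = None) -> dict[str, ClimateTable]:
    """Generate site monthly Tmax, precipitation, and a 1-month drought index.

    Tmax is a seasonal climatology plus an AR(1) anomaly plus a linear
    warming trend after the break year. Precipitation is gamma-distributed
    around the dry-summer seasonal cycle. The SPEI-like index is the
    per-calendar-month z-score of (precip z − w · Tmax z): positive wet,
    negative dry, mean 0 and SD 1 by construction.

    Climate covers ``start_year − 1`` .. ``end_year`` so the previous-year
    months of the first ring are available.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    years = np.arange(params.start_year - 1, params.end_year + 1)
    n = len(years)

    # AR(1) anomalies, marginal SD tmax_anom_sd, iterated through all months
    phi = params.tmax_anom_ar1
    innov_sd = params.tmax_anom_sd * np.sqrt(1 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n * 12)
    anom = np.empty(n * 12)
    anom[0] = rng.normal(0.0, params.tmax_anom_sd)
    for i in range(1, n * 12):
        anom[i] = phi * anom[i - 1] + eps[i]
    anom = anom.reshape(n, 12)
    trend = params.tmax_trend * np.maximum(0, years - params.trend_break_year) / 10.0
    tmax = TMAX_CLIMATOLOGY[None, :] + anom + trend[:, None]

    shape = params.precip_gamma_shape
    precip = rng.gamma(shape, PRECIP_CLIMATOLOGY[None, :] / shape, size=(n, 12))

    d = _month_z(precip) - params.spei_tmax_weight * _month_z(tmax)
    spei = _month_z(d)

    return {
        "tmax": ClimateTable("tmax", years, tmax),
        "precip": ClimateTable("precip", years, precip),
        "spei": ClimateTable("spei", years, spei),
    }


def gen_climate_grid(
    site: ClimateTable,
    params: SyntheticParams,
    seed: int | None = None,
    lats: np.ndarray | None = None,
    lons: np.ndarray | None = None,
    site_lat: float = 34.2,
    site_lon: float = 36.1,
    decay_deg: float = 10.0,
    anom_sd: float | None = None,
) -> GridField:
    """Gridded variant of a site series with spatially decaying coherence.

    Each cell's series is the site climatology plus a mixture
    ``a·(site anomaly) + sqrt(1−a²)·(own noise)`` with mixing weight
    ``a = exp(−distance/decay_deg)``, so the correlation of a cell with the
    site series decays with great-circle-ish (planar degree) distance.
    """
    rng = np.random.default_rng((params.seed if seed is None else seed) + 7919)
    if lats is None:
        lats = np.arange(25.0, 45.0, 2.0)
    if lons is None:
        lons = np.arange(26.0, 46.0, 2.0)
    clim = np.nanmean(site.values, axis=0)  # (12,)
    anomaly = site.values - clim[None, :]
    sd = float(np.nanstd(anomaly)) if anom_sd is None else anom_sd
    dist = np.sqrt(
        (lats[:, None] - site_lat) ** 2 + (lons[None, :] - site_lon) ** 2
    )
    a = np.exp(-dist / decay_deg)  # (nlat, nlon)
    own = rng.normal(0.0, sd, size=(len(site.years), 12, len(lats), len(lons)))
    vals = (
        clim[None, :, None, None]
        + a[None, None, :, :] * anomaly[:, :, None, None]
        + np.sqrt(1 - a**2)[None, None, :, :] * own
    )
    return GridField(
        variable=site.variable, years=site.years, lats=lats, lons=lons, values=vals
    )


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------


def _driver_zscores(climate: dict[str, ClimateTable], params: SyntheticParams):
    """Per-growth-year standardized climate drivers over the analysis span."""
    years = params.years
    tmax, precip, spei = climate["tmax"], climate["precip"], climate["spei"]
    for ct in (tmax, precip):
        if years.min() < ct.years.min() or years.max() > ct.years.max():
            raise ValidationError("climate does not span the anatomy years")
    sel = np.searchsorted(tmax.years, years)
    may_p = precip.values[np.searchsorted(precip.years, years), 4]
    apr_oct_t = tmax.values[sel][:, 3:10].mean(axis=1)
    gs_spei = spei.values[np.searchsorted(spei.years, years), 4:9].mean(axis=1)

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    return z(may_p), z(apr_oct_t), gs_spei


def _ring_cells(
    rng: np.random.Generator,
    n_cells: int,
    targets: np.ndarray,
    cell_noise_sd: float,
) -> np.ndarray:
    """Cell values along one radial file.

    A smooth intra-ring curve is obtained by linear interpolation of the
    sector targets at sector midpoints, then renormalised per sector so the
    mean of the cells inside each sector equals its target exactly (targets
    are defined as sector means); multiplicative lognormal cell noise is
    applied last.
    """
    S = len(targets)
    pos = (np.arange(1, n_cells + 1) - 0.5) / n_cells
    mids = (np.arange(S) + 0.5) / S
    vals = np.interp(pos, mids, targets)
    sec = np.ceil(pos * S).astype(int) - 1
    sums = np.bincount(sec, weights=vals, minlength=S)
    counts = np.bincount(sec, minlength=S)
    occupied = counts > 0
    scale = np.ones(S)
    scale[occupied] = targets[occupied] / (sums[occupied] / counts[occupied])
    vals = vals * scale[sec]
    if cell_noise_sd > 0:
        vals = vals * np.exp(rng.normal(0.0, cell_noise_sd, size=n_cells))
    return vals


def gen_anatomy(
    climate: dict[str, ClimateTable],
    params: SyntheticParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a per-cell anatomical table driven by the climate series.

    Per tree, year and sector the target LD is
    ``base_ld[s] · exp(β_P·z(May precip) + β_T·z(Apr–Oct Tmax) + tree + ε)``
    with ε idiosyncratic per tree×year×sector, plus a common level step of
    ``ld_break_step_sd`` tree-year log SDs from the break year onwards (the
    regime shift the changepoint test must detect); CWT uses the same
    drivers scaled by ``cwt_beta_scale`` against larger relative noise. Cells per
    file are Poisson with a mean that shrinks in dry (negative growing-
    season drought index) years, exercising cell-poor latewood rings.
    """
    rng = np.random.default_rng((params.seed if seed is None else seed) + 104729)
    z_p, z_t, gs_spei = _driver_zscores(climate, params)
    years = params.years
    S = params.n_sectors
    base_ld = np.asarray(params.base_ld_profile, dtype=float)
    base_cwt = np.asarray(params.base_cwt_profile, dtype=float)

    common = params.beta_precip_may * z_p + params.beta_tmax_summer * z_t
    sd_annual = np.sqrt(
        params.beta_precip_may**2 + params.beta_tmax_summer**2 + params.noise_sd**2
    )
    common = common + (
        params.ld_break_step_sd * sd_annual * (years >= params.trend_break_year)
    )
    common_cwt = params.cwt_beta_scale * common

    tree_eff = rng.normal(0.0, params.tree_effect_sd, size=params.n_trees)
    tree_eff_cwt = rng.normal(0.0, params.tree_effect_sd, size=params.n_trees)

    rows_tree, rows_core, rows_year, rows_file, rows_rank = [], [], [], [], []
    rows_ld, rows_cwt = [], []
    lo, hi = params.files_per_ring
    for ti in range(params.n_trees):
        tree_id = f"T{ti + 1:02d}"
        core_id = f"{tree_id}a"
        for yi, year in enumerate(years):
            eps_ld = rng.normal(0.0, params.noise_sd, size=S)
            eps_cwt = rng.normal(0.0, params.cwt_noise_sd, size=S)
            target_ld = base_ld * np.exp(common[yi] + tree_eff[ti] + eps_ld)
            target_cwt = base_cwt * np.exp(
                common_cwt[yi] + tree_eff_cwt[ti] + eps_cwt
            )
            n_files = int(rng.integers(lo, hi + 1))
            lam = params.cells_per_file * np.exp(
                params.drought_cell_sensitivity * gs_spei[yi]
            )
            for fi in range(n_files):
                n_cells = max(3, int(rng.poisson(lam)))
                ld = _ring_cells(rng, n_cells, target_ld, params.cell_noise_sd)
                cwt = _ring_cells(rng, n_cells, target_cwt, params.cwt_cell_noise_sd)
                rows_tree.append(np.repeat(tree_id, n_cells))
                rows_core.append(np.repeat(core_id, n_cells))
                rows_year.append(np.repeat(year, n_cells))
                rows_file.append(np.repeat(f"f{fi + 1:02d}", n_cells))
                rows_rank.append(np.arange(1, n_cells + 1))
                rows_ld.append(ld)
                rows_cwt.append(cwt)
    return pd.DataFrame(
        {
            "tree": np.concatenate(rows_tree),
            "core": np.concatenate(rows_core),
            "year": np.concatenate(rows_year).astype(int),
            "file": np.concatenate(rows_file),
            "rank": np.concatenate(rows_rank).astype(int),
            "ld": np.concatenate(rows_ld),
            "cwt": np.concatenate(rows_cwt),
        }
    )


# ---------------------------------------------------------------------------
# ring widths
# ---------------------------------------------------------------------------


def gen_ringwidths(
    climate: dict[str, ClimateTable],
    params: SyntheticParams,
    seed: int | None = None,
) -> RingWidthSet:
    """Generate ring widths with an age trend and a May–Jun precipitation signal.

    width = (w0·exp(−age/τ) + w∞) · exp(β·z(May–Jun precip) + AR(1) noise),
    per-core age offsets making trees different ages at 1963. The negative-
    exponential geometric trend is what spline detrending must remove.
    """
    rng = np.random.default_rng((params.seed if seed is None else seed) + 224737)
    precip = climate["precip"]
    years = params.years
    sel = np.searchsorted(precip.years, years)
    mj = precip.values[sel][:, 4:6].sum(axis=1)
    z_mj = (mj - mj.mean()) / mj.std(ddof=1)

    series: dict[str, tuple[int, np.ndarray]] = {}
    for c in range(params.n_cores_rw):
        age0 = rng.uniform(60.0, 150.0)
        ages = age0 + np.arange(len(years))
        trend = 2.5 * np.exp(-ages / 80.0) + 0.4
        noise = np.empty(len(years))
        noise[0] = rng.normal(0.0, params.rw_noise_sd)
        for i in range(1, len(years)):
            noise[i] = 0.3 * noise[i - 1] + rng.normal(
                0.0, params.rw_noise_sd * np.sqrt(1 - 0.3**2)
            )
        w = trend * np.exp(params.rw_beta_precip * z_mj + noise)
        series[f"C{c + 1:02d}"] = (int(years[0]), w)
    return RingWidthSet(series=series)
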