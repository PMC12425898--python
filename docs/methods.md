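# Methods

This note records the models, numerical choices and open design decisions
behind `qwa`, and what the synthetic-data tests do and do not demonstrate.

## Sector tracheidograms

A tracheidogram is the radial profile of a cell parameter along one ring.
Rings hold different cell counts, so profiles are standardized by relative
position: the i-th of n cells sits at (i − ½)/n ∈ (0, 1). The half-offset
keeps cells strictly inside the ring and — together with the half-open
sector intervals ((s−1)/S, s/S] — guarantees no cell ever lands on a
sector boundary. Positions are index-based, not cumulative-distance-based:
per-cell radial extents are often unavailable, and index positions are the
standard tracheidogram normalization; a distance-based variant could be
slotted in at `assign_relative_positions` without touching the rest.

Sector values are means of the cells inside each sector. A ring with fewer
cells than sectors leaves sectors empty; these are filled by evaluating
the piecewise-linear (position, value) polyline at the sector midpoint and
flagged `interpolated`, so cell-poor latewood rings are retained but
auditable. When the cell count is an exact multiple of the sector count
the mapping is exact (no flags) and preserves the ring mean.

Cells are averaged within radial files first and then across files, never
pooled, so files with many cells do not dominate the ring profile. Ten
files per ring is the recommended replication; below six a stronger
warning is logged, and the sample depth is carried through to the
chronologies.

### Outlier screening

Manual visual screening is replaced by a deterministic, fully reported
rule. For each ring and parameter, a cell's deviation is measured from the
ring's local level — the median of cells in the same relative-position
decile, interpolated linearly between decile midpoints (deciles with < 5
cells are skipped; rings with no usable decile fall back to the pooled
median). Judging deviations against this local profile keeps the steep
earlywood→latewood gradient itself from being flagged. A cell is removed
when its |residual| exceeds

- k × 1.4826 × MAD of the ring's residuals (k = 3 by default; the scaled
  mean absolute deviation, 1.2533 × mean|r|, substitutes when the MAD
  degenerates to zero), **and**
- 30% of the local level.

The relative floor reflects what anatomical artifacts look like: merged or
mis-detected cells are wrong by large factors, while the piecewise-linear
level model can misfit a sharp latewood transition by up to ~25% even on
noise-free data. Without the floor, any spread-based threshold eventually
truncates clean structured rings. On default synthetic data the screen
removes ~2.5% of cells and leaves the degenerate (noise-free) generator
output untouched. Every removal is returned in a report table
(tree/core/year/file/rank/parameter/value).

## Chronologies and signal statistics

Tree series are z-scored (sample SD, n − 1) over the common analysis
period; values outside the period are scaled with the period's constants.
Site sector chronologies are arithmetic means of the z-scores per year
(sample depth recorded; a year with no trees is missing, never zero).
Ring-width chronologies instead use the Tukey biweight robust mean
(c = 9, iterated from the median with MAD scale to 10⁻⁶), which discounts
outlier cores; on a two-core year it equals the arithmetic mean exactly.

Signal statistics follow the classical formulations: Rbar is the mean of
all pairwise Pearson correlations over pairwise-complete years (≥ 10
overlapping years per pair; short pairs are excluded with a warning rather
than failing the whole statistic), EPS = n·r̄/(n·r̄ + 1 − r̄) and
SNR = n·r̄/(1 − r̄), so EPS = SNR/(1 + SNR) holds identically. EPS values
recomputed from published six-tree Rbar values reproduce the published
EPS table to the printed precision; published SNR values in that table are
*not* consistent with the standard formula at n = 6 (they imply an
undocumented effective sample size), so SNR is reported from the standard
formula and the discrepancy is left visible rather than imitated. The
descriptive "mean ± SD" per sector is the mean over all tree×year raw
values and the SD of the per-year site-mean series.

The changepoint comparison (`split_group_test`) is a one-way fixed-effects
ANOVA of years before vs from the split year on (equivalent to a pooled
t-test, F = t²). Published group definitions for such splits sometimes
overlap at the boundary year; here the boundary year always opens the
second group.

## Ring-width standardization

The power transform regresses log local spread |x_t − x_{t−1}| on log
local mean (x_t + x_{t−1})/2; the optimal exponent is p = 1 − slope,
clamped to [−1, 1]. The output uses the Box–Cox form (x^p − 1)/p, which is
monotone increasing for every p — a plain x^p silently *inverts* the
series when the estimated p goes negative, which the slope regression can
produce on strongly heteroscedastic series. |p| < 0.05 falls back to
log(x).

Detrending fits a cubic smoothing spline (scipy's penalized
`make_smoothing_spline`) with penalty λ chosen from the continuous
frequency-response relation A(ω) = 1/(1 + λω⁴): amplitude 0.5 at
wavelength 0.66·n gives λ = (0.66·n/2π)⁴. The response is verified
empirically in the tests on trend-plus-sinusoid constructions, measured
over the interior half of the series (natural-spline boundary behaviour
inflates apparent amplitude near the ends); interior transmission at the
cutoff wavelength is 0.51, and wavelengths of n/10 pass essentially
untouched (> 99%). Indices are ratios to the fit; a non-positive fit
raises with advice to power-transform first (the detrending driver shifts
log-scale series positive before dividing).

## Climate correlations

The month axis has 24 slots (previous-year January … current-year
December); the default analysis window is previous-March … current-October
(20 slots), the physiologically plausible span for Mediterranean conifers.
Correlations are Pearson on pairwise-complete years (minimum 10), with
exact two-tailed p from the t-transform t = r√((n−2)/(1−r²)); the critical
r at n = 57, α = 0.05 is 0.261. No multiple-testing adjustment is applied
by default, matching common practice of per-cell p ≤ 0.05 masks;
Benjamini–Hochberg is available behind a flag for reanalysis. Seasonal
windows aggregate by mean for temperature and drought indices and by sum
for precipitation (totals are the physical quantity); the length-1 scan
row reproduces the monthly analysis bit for bit because both run through
the same kernel. Optimal windows maximize |r|, breaking ties toward the
shorter window and then the later end month. The high-pass option
first-differences *both* the chronology and the aggregated climate series,
so both sides retain only interannual variance. Spatial correlation maps
apply the same kernel per grid cell over a fixed seasonal window.

## Synthetic generator

The generator reproduces statistical structure, not xylogenesis: no
cambial kinetics are modelled. Site climate is a Mediterranean-mountain
seasonal cycle: monthly Tmax = climatology + AR(1) anomalies (φ = 0.5,
marginal SD 1 °C) + a linear warming trend after the 1992 break year
(+0.5 °C/decade); precipitation is gamma-distributed (shape 3) around a
dry-summer cycle; the drought index is the per-month z-score of
(precip z − 0.5 · Tmax z), standard normal per calendar month by
construction. The gridded variant mixes the site anomaly with independent
noise, with mixing weight exp(−distance/10°), so coherence with the site
decays spatially.

Anatomy targets are multiplicative on the log scale, keeping values
positive and making SD-scaled effect sizes interpretable:

    LD(tree, year, sector) = base_LD[sector] · exp(βP·z(May precip)
        + βT·z(Apr–Oct Tmax) + step·1[year ≥ 1992] + tree + ε)

with βP = +0.06, βT = −0.08, tree-level spread 0.05, idiosyncratic
tree×year×sector noise 0.12, and a common step of −0.8 tree-year log SDs
at the break — the regime shift the changepoint test must detect. These
defaults were set by a variance budget so that chronology–climate
correlations land near |r| ≈ 0.4–0.7 and the lumen-diameter Rbar is an
order of magnitude above the wall-thickness Rbar (CWT uses the same
drivers scaled by 0.15 against noise 0.10, reproducing the weak-CWT
contrast). Note the step and warming trend add shared variance, so
unfiltered Rbar on full defaults (~0.5) exceeds the trend-free common-
signal share ((βP²+βT²)/(βP²+βT²+σ²) ≈ 0.41), which the tests verify on a
trend- and step-free configuration where the algebra is exact.

Cells are drawn along a smooth intra-ring curve (sector targets
interpolated at sector midpoints) that is renormalised per sector so each
sector's cell mean equals its target exactly — this makes the zero-noise
generator exactly invertible by the pipeline, a key identity test. Cell
counts per file are Poisson (mean 40), shrinking in dry years; files per
ring are uniform on 10–14. Ring widths follow a negative-exponential age
curve (2.5·e^(−age/80) + 0.4 mm) times exp(0.25·z(May–Jun precip) + AR(1)
noise), per-core age offsets of 60–150 years.

What passing tests show — and do not. Parameter recovery on this generator
demonstrates that the pipeline's statistics are unbiased and powerful
under the assumed structure (log-linear climate effects, stationary noise,
correct dating). Real data add ring-boundary errors, missing/wedging
rings, within-ring geometry the index-based positions ignore, and
non-stationary climate responses; none of these are emulated, so green
tests here do not certify behaviour under those pathologies.

## Problem sizes and determinism

Default test and acceptance runs use the study-scale configuration
(6 trees × 57 years × 10–14 files × ~40 cells ≈ 165k cells; ~2 s per
replicate through the full anatomy pipeline) with 10 fixed replicate seeds
for recovery checks and 10 for null calibration; unit tests use a 4-tree ×
35-year variant. All generator output and every pipeline artifact are
bit-reproducible given (params, seed); the run manifest deliberately
excludes timestamps so repeated runs are byte-identical.

## Known limitations

- Sector positions are cell-index-based; no lobate-growth reconciliation
  or wedge-ring handling (cores with such features should be excluded
  upstream).
- The outlier screen's 30% relative floor is tuned for gross measurement
  artifacts; subtle systematic errors (e.g. consistent wall-boundary
  misplacement) pass through.
- SNR is reported from the standard formula only (see above).
- The drought index consumed here is an input or a z-score construction;
  no physically based SPEI computation from raw climate is included.
- No partial-correlation (secondary-variable) seasonal analysis; plain
  Pearson values only.
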