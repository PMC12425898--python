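# qwa — quantitative wood anatomy dendroclimatology

`qwa` is a Python toolkit for extracting climate signals from the cellular
anatomy of conifer tree rings. It is aimed at dendroclimatologists working
with ROXAS/RAPTOR-style per-cell measurements (tracheid lumen diameter and
cell wall thickness) who want a reproducible path from raw cell tables to
intra-ring **sector chronologies**, chronology **signal statistics**, and
**monthly/seasonal/spatial climate correlations** — the workflow used to
evaluate drought-sensitive species such as Mediterranean mountain junipers
as hydroclimate archives.

## What it computes

**Sector tracheidograms.** Each ring's radial files of cells are mapped to
relative positions ((i − ½)/n for the i-th of n cells), split into ten
equidistant sectors (I = earlywood at the ring start … X = latewood at the
ring end), averaged within and then across files (≥ 10 files recommended,
6 minimum), after a deterministic position-aware MAD outlier screen that
replaces manual visual checking and reports every removal.

**Chronologies and signal strength.** Per-tree sector series are
z-transformed over a common period and averaged into site chronologies
(arithmetic mean for anatomy; Tukey biweight robust mean for ring widths).
Common-signal strength is summarised by

- Rbar: mean pairwise Pearson correlation among tree series
  (pairwise-complete, ≥ 10 overlapping years per pair),
- EPS = n·r̄ / (n·r̄ + 1 − r̄), the expressed population signal,
- SNR = n·r̄ / (1 − r̄), so that EPS = SNR/(1 + SNR),
- AR1, the chronology's lag-1 autocorrelation,

plus a two-group one-way ANOVA (`split_group_test`) for a level shift
around a changepoint year.

**Ring-width standardization.** Widths are read from Tucson `.rwl` files
(both the 999/0.01 mm and −9999/0.001 mm dialects), variance-stabilized by
a spread-vs-level power transform (Box–Cox form, exponent p = 1 − slope of
log spread on log level), and detrended by a cubic smoothing spline whose
frequency-response amplitude is 50% at a wavelength of 66% of the series
length; indices are the ratio of width to fit (mean ≈ 1).

**Climate correlations.** Chronologies are correlated with monthly climate
(Tmax, precipitation, a 1-month drought index such as SPEI-1) on a 24-slot
month axis from previous-year January to current-year December (analysis
window previous-March … current-October by default); seasonal aggregates
of 1–19 months are scanned (means for temperature/drought, sums for
precipitation) and the |r|-optimal window reported; gridded fields yield
correlation maps with exact two-tailed t-based significance. First-
difference (high-pass) variants of every analysis are available.

**Synthetic data.** Because per-cell field data are rarely deposited,
`qwa.synthetic` generates climate and climate-driven cell anatomy with the
statistical structure the analysis assumes (6 trees × 1963–2019 by
default, declining lumen profile 22.4 → 3.7 µm, weak wall-thickness common
signal, a post-1992 warming/drying regime shift) so every stage is
testable end to end.

## Worked example

```python
import qwa
from qwa.chronology import chronology_frame, sector_chronology, split_group_test
from qwa.climate import best_season, seasonal_scan

params = qwa.SyntheticParams(seed=42)
climate = qwa.gen_climate(params)
matrix = qwa.build_sector_matrix(qwa.gen_anatomy(climate, params))
stats = qwa.chronology_stats(matrix, "ld", period=(1963, 2019))
print(stats.loc[["I", "X", "Mean"], ["rbar", "eps", "snr", "ar1"]].round(3))
```

```
         rbar    eps    snr    ar1
sector
I       0.581  0.893  8.305  0.566
X       0.504  0.859  6.098  0.228
Mean    0.527  0.868  6.830  0.447
```

The lumen-diameter chronologies share a strong common signal (the same
table for `"cwt"` gives a mean Rbar of 0.060 — wall thickness is largely
idiosyncratic). Scanning seasonal windows and testing the regime shift:

```python
chron = chronology_frame(sector_chronology(matrix, "ld", period=(1963, 2019)))
print(best_season(seasonal_scan(chron["X"], climate["tmax"]))[["label", "r"]])
res = split_group_test(chron.mean(axis=1), 1992)
print(res.f_stat, res.p_value)
```

```
label    May-Oct
r      -0.798885
43.69  1.63e-08
```

The latewood sector correlates at r = −0.80 with May–October maximum
temperature (heat/drought stress narrows the lumen), and mean lumen
diameter drops sharply from 1992 on (ANOVA F = 43.7, p ≈ 2·10⁻⁸) — the
generator's injected warming/drying shift, recovered by the pipeline. The
scripts in `examples/` walk through each capability and print these
numbers; `qwa simulate`, `qwa sectors`, `qwa chron`, `qwa rwchron` and
`qwa run --config config.yaml` expose the same pipeline from the shell.

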