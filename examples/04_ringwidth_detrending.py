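"""Ring-width standardization: power transform, spline detrending, biweight.

Each core's widths are variance-stabilized (spread-vs-level power
transform), divided by a cubic smoothing spline whose frequency response is
50% at a wavelength of 66% of the series length, and the resulting unit-mean
indices are averaged with the Tukey biweight robust mean.
"""

import numpy as np

import qwa
from qwa.chronology import detrend_ringwidths, power_transform, rw_chronology

params = qwa.SyntheticParams(seed=42)
climate = qwa.gen_climate(params)
rws = qwa.gen_ringwidths(climate, params)

first, w = rws.series["C01"]
pt = power_transform(np.maximum(w, 1e-6))
print(f"core C01: {len(w)} rings from {first}, "
      f"optimal power p = {pt.power:.2f} (slope {pt.slope:.2f})")

indices = detrend_ringwidths(rws)
chron = rw_chronology(indices, method="biweight")
series = chron.as_series()
print(f"site chronology: {len(series)} years, mean index "
      f"{series.mean():.3f}, depth {int(chron.depth.max())} cores")

precip = climate["precip"]
sel = np.searchsorted(precip.years, series.index.to_numpy())
may_jun = precip.values[sel][:, 4:6].sum(axis=1)
r = np.corrcoef(series.to_numpy(), may_jun)[0, 1]
print(f"correlation with May–Jun precipitation: r = {r:.2f} "
      f"(critical r at p=0.05: {qwa.critical_r(len(series)):.3f})")
# The age trend is removed by the spline; the climate signal survives in
# the dimensionless index and is recovered above the significance line.
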