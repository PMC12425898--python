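"""Generate a synthetic juniper QWA dataset and write it to disk.

The generator emulates the statistical structure of a semi-arid mountain
stand: 6 trees × 57 rings (1963–2019), 10–14 radial files per ring, a
declining intra-ring lumen profile, monthly climate with a post-1992
warming/drying shift, and climate-driven lumen variability.
"""

from pathlib import Path

import qwa
from qwa.io_formats import write_cell_table, write_monthly_climate, write_rwl

out = Path("sim")
out.mkdir(exist_ok=True)

params = qwa.SyntheticParams(seed=42)
climate = qwa.gen_climate(params)
cells = qwa.gen_anatomy(climate, params)
rws = qwa.gen_ringwidths(climate, params)

write_cell_table(cells, out / "cells.csv")
write_rwl(rws, out / "rw.rwl")
for var, table in climate.items():
    write_monthly_climate(table, out / f"climate_{var}.csv")

print(f"cells:        {len(cells):>7} rows "
      f"({cells['tree'].nunique()} trees, years "
      f"{cells['year'].min()}–{cells['year'].max()})")
print(f"ring widths:  {len(rws.series):>7} cores")
print(f"climate:      {len(climate)} variables, years "
      f"{climate['tmax'].years[0]}–{climate['tmax'].years[-1]}")
print(f"written to {out}/")
# Each cell row is one tracheid: its ring, radial file, rank from the ring
# start, lumen diameter (µm) and wall thickness (µm).
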