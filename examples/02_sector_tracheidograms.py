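"""From per-cell measurements to ten-sector tracheidograms.

Each ring's radial files are standardized onto ten equidistant sectors
(I = earlywood at the ring start ... X = latewood at the ring end) and
averaged, after a position-aware MAD outlier screen.
"""

import numpy as np

import qwa

params = qwa.SyntheticParams(seed=42)
climate = qwa.gen_climate(params)
cells = qwa.gen_anatomy(climate, params)

matrix = qwa.build_sector_matrix(cells, n_sectors=10, min_files=10, mad_k=3.0)
report = matrix.attrs["outlier_report"]

print(f"matrix: {matrix.sizes['tree']} trees × {matrix.sizes['year']} years "
      f"× {matrix.sizes['sector']} sectors")
print(f"outlier screen removed {len(report)} of {len(cells)} cells "
      f"({100 * len(report) / len(cells):.2f}%)")

labels = matrix.attrs["sector_labels"]
ld = matrix["ld"].sel(tree="T01", year=2000).values
cwt = matrix["cwt"].sel(tree="T01", year=2000).values
print("\ntree T01, ring 2000 (sector means):")
print("sector:", "  ".join(f"{lab:>5}" for lab in labels))
print("LD µm: ", "  ".join(f"{v:5.1f}" for v in ld))
print("CWT µm:", "  ".join(f"{v:5.2f}" for v in cwt))
# LD falls and CWT rises from sector I to X — the earlywood→latewood
# anatomy of a conifer ring.
print("\nsite mean LD per sector (µm):",
      np.round(np.nanmean(matrix["ld"].values, axis=(0, 1)), 1))
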