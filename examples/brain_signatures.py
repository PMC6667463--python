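"""Compute region-specific MDM signatures from synthetic brain maps.

Builds a small synthetic brain (three bilateral regions, each with its own
linear qMRI~MTV law plus voxel noise), pools both hemispheres per region,
bins voxels along MTV, and fits the per-region MTV derivatives.
"""

import numpy as np

from mdmtv import (
    compute_signature,
    default_brain_spec,
    extract_roi_voxels,
    join_bilateral,
    simulate_brain,
)
from mdmtv.relaxivity import BinningConfig, bin_by_mtv, fit_dependency

spec = default_brain_spec(n_voxels=3000)
maps, labels = simulate_brain(spec, seed=11)

print("region           param   slope      intercept  adj R2   bins")
for name in ("thalamus", "pallidum", "frontal-wm"):
    rows = labels.region_table[labels.region_table["name"] == name]
    sides = [
        extract_roi_voxels(maps, labels, int(r.label), erosion_depth=1)
        for r in rows.itertuples()
    ]
    pooled = join_bilateral(sides[0], sides[1])  # hemispheres analysed jointly
    for param in ("R1", "MTsat"):
        dep = fit_dependency(bin_by_mtv(pooled, param, BinningConfig()))
        print(
            f"{name:<16} {param:<7} {dep.slope:<10.3f} {dep.intercept:<10.3f} "
            f"{dep.r2_adj:<8.3f} {dep.n_bins_used}"
        )

print()
print("Each slope is the region's MTV derivative of that qMRI parameter —")
print("one axis of its multidimensional relaxivity signature. Distinct")
print("regions show distinct slope vectors; adj R2 near 1 reflects the")
print("near-linear dependency of the binned medians on MTV.")
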