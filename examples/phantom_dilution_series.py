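"""Fit relaxivity signatures of pure components from a dilution series.

Simulates lipid-like phantom samples scanned at varying concentrations
(MTV values), takes the median per concentration, and fits the linear
qMRI~MTV law across samples — the phantom-style MDM computation.
"""

import numpy as np

from mdmtv import default_phantom_spec, simulate_phantom
from mdmtv.relaxivity import BinnedProfile, BinningConfig, fit_dependency

spec = default_phantom_spec()
table = simulate_phantom(spec, seed=3)

print("component  param  fitted slope  true slope")
for name, laws in spec.components.items():
    pure = table[table["component"] == name]
    for param in ("R1", "MTsat"):
        med = pure.groupby("mtv")[param].median()
        profile = BinnedProfile(
            param=param,
            regressor_median=med.index.to_numpy(float),
            q_median=med.to_numpy(float),
            q_mad=np.zeros(len(med)),
            counts=np.full(len(med), spec.replicates),
            total_voxels=len(pure),
            config=BinningConfig(),
        )
        dep = fit_dependency(profile)
        print(f"{name:<10} {param:<6} {dep.slope:>10.3f}  {laws[param][0]:>10.3f}")

print()
print("Each component has a distinct slope vector (its MDM signature);")
print("fitted slopes track the generating truth to within the noise.")
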