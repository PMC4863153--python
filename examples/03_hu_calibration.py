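"""CT Hounsfield units to materials: the stoichiometric calibration.

Maps HU values through the packaged Schneider-style 24-material /
41-interval segmentation and builds a voxel phantom from a toy HU grid.
"""

import numpy as np

from iondose import (build_default_calibration, hounsfield_from_mu,
                     material_at, phantom_from_hu)

# HU from attenuation coefficients: air -> -1000, water -> 0
mu_water, mu_air = 0.1928, 0.000216
print("HU(air)   =", hounsfield_from_mu(mu_air, mu_water, mu_air))
print("HU(water) =", hounsfield_from_mu(mu_water, mu_water, mu_air))

calib = build_default_calibration()
print(f"calibration: {len(calib.segments)} intervals, "
      f"{len(calib.material_ids())} materials, "
      f"HU in [{calib.hu_min:g}, {calib.hu_max:g}]")
for hu in (-1000, -700, -50, 0, 60, 400, 1500, 3000):
    mat, rho = material_at(float(hu), calib)
    print(f"  HU {hu:6d} -> {mat:12s} rho = {rho:6.3f} g/cm3")

# a toy CT: water with a bone-like insert and an air pocket
hu = np.zeros((10, 10, 30))
hu[:, :, 10:14] = 1200.0
hu[4:6, 4:6, 20:22] = -1000.0
phantom = phantom_from_hu(hu, (2.0, 2.0, 2.0))
names = [m.name for m in phantom.materials]
print("phantom materials:", names)

# Within each HU interval the composition is fixed while the density
# scales linearly with the actual HU value, so dose calculations keep a
# continuous density map with only 24 distinct material compositions.
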