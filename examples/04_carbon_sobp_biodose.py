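"""Biologically optimized carbon-ion spread-out Bragg peak.

Simulates mono-energetic carbon components in water, scores the
mixed-field dose-weighted LQ coefficients, and optimizes the component
weights so the RBE-weighted dose is flat at 3 Gy (RBE) over the
60-120 mm target (a 6 cm cube centred at 9 cm depth, in 1D).

Reduced statistics here (3000 primaries/component) for a quick demo.
"""

import logging

import numpy as np

from iondose import DEFAULT_PHOTON_REFERENCE, optimize_sobp
from iondose.fixtures import carbon_sobp_components

logging.getLogger("iondose").setLevel(logging.ERROR)

target = (60.0, 120.0)
comps, table = carbon_sobp_components(target_depth_mm=target,
                                      n_components=12,
                                      n_primaries=3000, seed=4)
res = optimize_sobp(comps, target, 3.0, DEFAULT_PHOTON_REFERENCE)

m = res.target_mask
print(f"components              : {len(comps)} "
      f"({comps[0].energy:.0f}-{comps[-1].energy:.0f} MeV/u)")
print(f"mean D_RBE in target    : {res.d_rbe[m].mean():.3f} Gy (RBE)")
print(f"max |D_RBE - 3 Gy(RBE)| : {res.max_deviation:.3f} Gy (RBE)")
print(f"mean absorbed dose      : {res.dose[m].mean():.3f} Gy")
print(f"alpha_bar proximal/distal: {res.alpha_bar[m][0]:.3f} / "
      f"{res.alpha_bar[m][-1]:.3f} Gy^-1")

# The absorbed dose inside the target is well below 3 Gy: the rising
# alpha_bar toward the distal edge (slow, high-LET carbon ions) means
# less physical dose is needed there for the same biological effect --
# the signature shape of a biologically optimized SOBP.
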