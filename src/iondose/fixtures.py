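"""Deterministic generators for test and example inputs.

Everything here is synthetic but shaped like the real thing: LQ coefficient
tables with the qualitative energy dependence of ion radiobiology
(carbon-like alpha rising steeply as the ion slows; proton-like nearly
flat), threshold-plateau activation cross sections, analytic Bragg-like
curves with a known peak for metrics tests, and water/layered phantoms.
No randomness unless a seed is passed explicitly.
"""

from __future__ import annotations

import numpy as np

from .biodose import LQCoefficientTable
from .materials import VoxelPhantom, make_slab_phantom
from .monitor import CrossSectionTable, HALF_LIVES_S
from .transport import DepthDoseCurve


def carbon_like_lq_table(n_points: int = 80) -> LQCoefficientTable:
    """Carbon-ion-like LQ coefficients: alpha rises from ~0.1 Gy^-1 at
    high energy toward ~1.1 Gy^-1 as the ion slows (mirroring the LET
    increase), beta mildly rising as well."""
    e = np.geomspace(1.0, 600.0, n_points)
    alpha = 0.10 + 1.00 / (1.0 + (e / 25.0) ** 1.3)
    beta = 0.010 + 0.040 / (1.0 + (e / 25.0) ** 1.3)
    return LQCoefficientTable("carbon", e, alpha, beta)


def proton_like_lq_table(n_points: int = 60) -> LQCoefficientTable:
    """Proton-like LQ coefficients: nearly constant, close to the photon
    reference, with a mild low-energy rise."""
    e = np.geomspace(0.5, 300.0, n_points)
    alpha = 0.10 + 0.05 / (1.0 + (e / 3.0) ** 1.5)
    beta = np.full_like(e, 0.05)
    return LQCoefficientTable("proton", e, alpha, beta)


def reference_photon_lq_table(n_points: int = 20) -> LQCoefficientTable:
    """alpha, beta identically at the photon reference (0.1, 0.05) — in
    this degenerate table the RBE-weighted dose equals the absorbed dose."""
    e = np.geomspace(0.5, 600.0, n_points)
    return LQCoefficientTable("reference", e, np.full_like(e, 0.1),
                              np.full_like(e, 0.05))


def oxygen15_cross_section() -> CrossSectionTable:
    """Threshold-plateau surrogate for 16O(p,x)15O: zero below the
    ~16.8 MeV threshold, rising to a ~70 mb plateau."""
    e = np.linspace(0.0, 250.0, 126)
    sigma = np.where(e > 16.8, 70.0 * (1.0 - np.exp(-(e - 16.8) / 12.0)),
                     0.0)
    return CrossSectionTable("16O(p,x)15O", "O15", HALF_LIVES_S["O15"],
                             8, e, sigma)


def carbon11_cross_section() -> CrossSectionTable:
    """Threshold-plateau surrogate for 12C(p,x)11C (threshold ~20 MeV,
    ~80 mb plateau)."""
    e = np.linspace(0.0, 250.0, 126)
    sigma = np.where(e > 20.0, 80.0 * (1.0 - np.exp(-(e - 20.0) / 15.0)),
                     0.0)
    return CrossSectionTable("12C(p,x)11C", "C11", HALF_LIVES_S["C11"],
                             6, e, sigma)


def box_cross_section(e_lo: float, e_hi: float, sigma_mb: float,
                      product: str = "O15",
                      target_z: int = 8) -> CrossSectionTable:
    """Box-function sigma(E): sigma_mb inside [e_lo, e_hi], zero outside
    (sharp edges resolved on a fine grid)."""
    eps = 1e-6
    e = np.array([0.0, e_lo - eps, e_lo, e_hi, e_hi + eps, 1000.0])
    s = np.array([0.0, 0.0, sigma_mb, sigma_mb, 0.0, 0.0])
    return CrossSectionTable(f"box[{e_lo},{e_hi}]", product,
                             HALF_LIVES_S.get(product, 100.0), target_z,
                             e, s)


def analytic_bragg_curve(
    peak_mm: float = 150.0,
    entrance_mm: float = 0.5,
    spacing_mm: float = 1.0,
    plateau: float = 1.0,
    peak_ratio: float = 4.0,
    peak_sigma_mm: float = 3.0,
    falloff_mm: float = 2.0,
    total_mm: float | None = None,
) -> DepthDoseCurve:
    """Smooth Bragg-like test curve with a known peak position: a flat
    entrance plateau, a Gaussian peak at ``peak_mm`` and a sigmoid distal
    falloff.  Used as a metrics fixture; not a physics model."""
    if total_mm is None:
        total_mm = peak_mm + 10.0 * falloff_mm + 20.0
    z = np.arange(entrance_mm, total_mm, spacing_mm)
    peak = (peak_ratio - 1.0) * np.exp(-0.5 * ((z - peak_mm)
                                               / peak_sigma_mm) ** 2)
    distal = 1.0 / (1.0 + np.exp((z - peak_mm - 2.0 * peak_sigma_mm)
                                 / falloff_mm))
    dose = plateau * (1.0 + peak) * distal
    return DepthDoseCurve(z, dose, np.zeros_like(z))


def carbon_sobp_components(
    target_depth_mm: tuple[float, float] = (60.0, 120.0),
    n_components: int = 12,
    n_primaries: int = 10_000,
    seed: int = 0,
    phantom: VoxelPhantom | None = None,
    lq_table: LQCoefficientTable | None = None,
    energy_sigma_fraction: float = 0.012,
):
    """Simulate mono-energetic carbon depth-dose components whose Bragg
    peaks span the target depth interval in water.

    Energies are chosen by inverting the CSDA range so the peaks cover
    the interval from the proximal to just past the distal target edge.
    The relative energy spread (default 1.2%) emulates the ripple-filter
    broadening used clinically for carbon SOBPs, without which the narrow
    carbon peaks would leave dose ripples between neighboring components.
    Returns (components, lq_table).
    """
    from .biodose import sobp_component_from_grid
    from .stopping import CARBON, energy_at_range
    from .transport import BeamSpec, TransportConfig, run_simulation
    from .materials import WATER

    z_lo, z_hi = target_depth_mm
    if phantom is None:
        phantom = make_slab_phantom([("water", z_hi + 40.0)],
                                    cross_section_mm=30.0, spacing_mm=1.0)
    if lq_table is None:
        lq_table = carbon_like_lq_table()
    ranges_cm = np.linspace(z_lo, z_hi + 2.0, n_components) / 10.0
    energies = [energy_at_range(r, CARBON, WATER) for r in ranges_cm]
    center = (phantom.extent_mm[0] / 2.0, phantom.extent_mm[1] / 2.0, 0.0)
    components = []
    for k, e in enumerate(energies):
        beam = BeamSpec(CARBON, e, n_primaries=n_primaries,
                        energy_sigma=energy_sigma_fraction * e,
                        spot_sigma_x=2.0, spot_sigma_y=2.0,
                        position=center)
        cfg = TransportConfig(rng_seed=seed * 1009 + k)
        grid = run_simulation(beam, phantom, cfg, lq_table=lq_table)
        components.append(sobp_component_from_grid(grid))
    return components, lq_table


def water_phantom(length_mm: float = 300.0, cross_section_mm: float = 40.0,
                  spacing_mm: float = 1.0) -> VoxelPhantom:
    return make_slab_phantom([("water", length_mm)], cross_section_mm,
                             spacing_mm)


def layered_phantom(spacing_mm: float = 1.0) -> VoxelPhantom:
    """Water / bone / water 100 / 20 / 180 mm test stack."""
    return make_slab_phantom(
        [("water", 100.0), ("bone", 20.0), ("water", 180.0)],
        cross_section_mm=40.0, spacing_mm=spacing_mm,
    )
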