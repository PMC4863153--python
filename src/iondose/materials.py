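"""Materials, Hounsfield-unit calibration and voxel phantoms.

A :class:`Material` bundles the elemental composition, bulk density, mean
excitation energy and electron density entering the Bethe-Bloch stopping
power.  CT images are mapped onto materials through an
:class:`HUCalibration`: a stoichiometric, Schneider-style segmentation of
the HU axis into a small set of tissue compositions, each segment carrying
a linear continuous density scaling so that the *real* per-voxel density
follows the HU value while the composition stays piecewise constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS

log = logging.getLogger(__name__)

#: Element symbol -> (Z, A, I_eV). I values follow the standard
#: Berger-Seltzer recommendations used for Bragg-additivity mixing.
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.98977, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.973762, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "Ar": (18, 39.948, 188.0),
    "K": (19, 39.0983, 190.0),
    "Ca": (20, 40.078, 191.0),
}

#: Mean excitation energy of liquid water used by default (eV). Overridable
#: per material; the chosen value is echoed in every run header.
WATER_I_DEFAULT_EV = 78.0


@dataclass(frozen=True)
class Material:
    """A homogeneous material of known composition and density.

    ``elements`` is a list of ``(Z, A, mass_fraction)`` triples; fractions
    must sum to one.  ``electron_density`` (electrons/cm^3) is derived from
    the composition at construction and re-checked against any provided
    value.
    """

    name: str
    elements: tuple[tuple[int, float, float], ...]
    density: float  # g/cm^3
    mean_excitation_energy: float  # eV
    electron_density: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"material {self.name!r} has empty composition")
        total = sum(w for _, _, w in self.elements)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total!r}, not 1"
            )
        if self.density <= 0:
            raise ValueError(f"density of {self.name!r} must be > 0")
        if self.mean_excitation_energy <= 0:
            raise ValueError(f"I of {self.name!r} must be > 0")
        ne = electron_density(self)
        if self.electron_density == 0.0:
            object.__setattr__(self, "electron_density", ne)
        elif abs(self.electron_density - ne) > 1e-9 * ne:
            raise ValueError(
                f"electron_density of {self.name!r} inconsistent with "
                f"composition: given {self.electron_density}, computed {ne}"
            )

    @property
    def z_over_a(self) -> float:
        """Mass-weighted <Z/A> (mol electrons per gram)."""
        return sum(w * z / a for z, a, w in self.elements)

    @property
    def mean_z(self) -> float:
        """Electron-weighted mean atomic number (used in C/Z)."""
        num = sum(w * z / a * z for z, a, w in self.elements)
        return num / self.z_over_a

    def with_density(self, density: float) -> "Material":
        return Material(self.name, self.elements, density,
                        self.mean_excitation_energy)


def electron_density(material: Material) -> float:
    """Electron density rho * N_Av * sum(w_i Z_i / A_i) in electrons/cm^3."""
    return material.density * CONSTANTS.avogadro * material.z_over_a


def bragg_additivity_i(elements: Iterable[tuple[int, float, float]]) -> float:
    """Mean excitation energy (eV) of a mixture by Bragg additivity:
    ln I = sum(w Z/A ln I_i) / sum(w Z/A)."""
    num = 0.0
    den = 0.0
    by_z = {z: i for _, (z, _, i) in zip(ELEMENTS, ELEMENTS.values())}
    for z, a, w in elements:
        i_el = by_z.get(z)
        if i_el is None:
            raise KeyError(f"no packaged I value for Z={z}")
        num += w * z / a * math.log(i_el)
        den += w * z / a
    return math.exp(num / den)


def make_material(
    name: str,
    composition: dict[str, float],
    density: float,
    mean_excitation_energy: float | None = None,
) -> Material:
    """Build a material from symbol->mass-fraction mapping (normalized)."""
    total = sum(composition.values())
    elems = tuple(
        (ELEMENTS[s][0], ELEMENTS[s][1], w / total)
        for s, w in sorted(composition.items(), key=lambda kv: ELEMENTS[kv[0]][0])
    )
    if mean_excitation_energy is None:
        mean_excitation_energy = bragg_additivity_i(elems)
    return Material(name, elems, density, mean_excitation_energy)


# -- built-in materials -----------------------------------------------------

WATER = make_material(
    "water", {"H": 2 * 1.008, "O": 15.999}, 1.0,
    mean_excitation_energy=WATER_I_DEFAULT_EV,
)
AIR = make_material(
    "air", {"N": 0.755, "O": 0.232, "Ar": 0.0128, "C": 0.000124}, 1.21e-3
)
BONE = make_material(
    "bone",
    {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
     "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225},
    1.85,
)
LUNG = make_material(
    "lung",
    {"H": 0.105, "C": 0.256, "N": 0.027, "O": 0.602, "Na": 0.001,
     "P": 0.002, "S": 0.003, "Cl": 0.002, "K": 0.002},
    0.26,
)
PMMA = make_material("pmma", {"H": 0.080538, "C": 0.599848, "O": 0.319614},
                     1.19)

BUILTIN_MATERIALS: dict[str, Material] = {
    m.name: m for m in (WATER, AIR, BONE, LUNG, PMMA)
}


# -- Hounsfield calibration -------------------------------------------------

def hounsfield_from_mu(mu_x: float, mu_water: float, mu_air: float) -> float:
    """HU from linear attenuation coefficients:
    ``1000 (mu_x - mu_water) / (mu_water - mu_air)``."""
    if mu_x < 0 or mu_water < 0 or mu_air < 0:
        raise ValueError("attenuation coefficients must be non-negative")
    denom = mu_water - mu_air
    if denom == 0.0:
        raise ValueError(
            f"degenerate HU denominator: mu_water={mu_water} equals "
            f"mu_air={mu_air}"
        )
    # ratio first: keeps the air endpoint exactly -1000 in floating point
    return 1000.0 * ((mu_x - mu_water) / denom)


@dataclass(frozen=True)
class HUSegment:
    """One half-open HU interval mapped to a single material with a linear
    density scaling about the interval center."""

    hu_low: float
    hu_high: float
    material_id: str
    nominal_density: float
    density_slope: float

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError(
                f"segment {self.material_id!r}: hu_low must be < hu_high"
            )
        if self.nominal_density < 0:
            raise ValueError("nominal_density must be >= 0")
        c = self.center
        for hu in (self.hu_low, self.hu_high):
            if self.nominal_density + self.density_slope * (hu - c) < 0:
                raise ValueError(
                    f"segment {self.material_id!r} reaches negative density"
                )

    @property
    def center(self) -> float:
        return 0.5 * (self.hu_low + self.hu_high)

    def density_at(self, hu: float) -> float:
        return self.nominal_density + self.density_slope * (hu - self.center)


@dataclass(frozen=True)
class HUCalibration:
    """Ordered HU segments tiling [hu_min, hu_max] plus the material set."""

    segments: tuple[HUSegment, ...]
    materials: dict[str, Material]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("calibration needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if a.hu_high != b.hu_low:
                raise ValueError(
                    f"calibration gap/overlap between {a.material_id!r} "
                    f"({a.hu_high}) and {b.material_id!r} ({b.hu_low})"
                )
        missing = {s.material_id for s in segs} - set(self.materials)
        if missing:
            raise ValueError(f"segments reference unknown materials {missing}")

    @property
    def hu_min(self) -> float:
        return self.segments[0].hu_low

    @property
    def hu_max(self) -> float:
        return self.segments[-1].hu_high

    def material_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.segments:
            if s.material_id not in seen:
                seen.append(s.material_id)
        return seen


def material_at(hu: float, calibration: HUCalibration) -> tuple[str, float]:
    """Material id and continuous density at a HU value.

    Out-of-range HU values are clamped to the calibration bounds with a
    logged warning.  The final segment is closed at its upper edge; all
    others are half-open ``[low, high)``.
    """
    if hu < calibration.hu_min or hu > calibration.hu_max:
        log.warning(
            "HU %.1f outside calibration [%g, %g]; clamping",
            hu, calibration.hu_min, calibration.hu_max,
        )
        hu = min(max(hu, calibration.hu_min), calibration.hu_max)
    segs = calibration.segments
    if hu >= segs[-1].hu_low:
        seg = segs[-1]
    else:
        lows = [s.hu_low for s in segs]
        idx = int(np.searchsorted(lows, hu, side="right")) - 1
        seg = segs[idx]
    return seg.material_id, seg.density_at(hu)


def load_calibration_csv(
    segments_csv: str | Path, compositions_csv: str | Path
) -> HUCalibration:
    """Load a calibration from the two-CSV external format
    (segments: hu_low,hu_high,material,nominal_density,density_slope;
    compositions: material,element,Z,A,mass_fraction)."""
    seg_df = pd.read_csv(segments_csv, comment="#")
    comp_df = pd.read_csv(compositions_csv, comment="#")
    materials: dict[str, Material] = {}
    for name, grp in comp_df.groupby("material"):
        elems = tuple(
            (int(r.Z), float(r.A), float(r.mass_fraction))
            for r in grp.itertuples()
        )
        total = sum(w for _, _, w in elems)
        elems = tuple((z, a, w / total) for z, a, w in elems)
        nominal = float(
            seg_df.loc[seg_df.material == name, "nominal_density"].iloc[0]
        )
        i_ev = (WATER_I_DEFAULT_EV if name == "water"
                else bragg_additivity_i(elems))
        materials[name] = Material(name, elems, max(nominal, 1e-6), i_ev)
    segments = tuple(
        HUSegment(float(r.hu_low), float(r.hu_high), str(r.material),
                  float(r.nominal_density), float(r.density_slope))
        for r in seg_df.itertuples()
    )
    return HUCalibration(segments, materials)


def build_default_calibration() -> HUCalibration:
    """The packaged synthetic Schneider-style table: 24 materials over 41
    HU intervals covering [-1000, 3500]."""
    data = resources.files("iondose") / "data"
    return load_calibration_csv(
        Path(str(data / "synthetic_schneider_segments.csv")),
        Path(str(data / "synthetic_schneider_compositions.csv")),
    )


# -- voxel phantoms ---------------------------------------------------------

@dataclass
class VoxelPhantom:
    """A 3D voxel grid of material indices with per-voxel density scaling.

    Voxel ``(i, j, k)`` occupies the half-open box
    ``[i dx, (i+1) dx) x [j dy, (j+1) dy) x [k dz, (k+1) dz)`` in phantom
    coordinates (mm).  ``density_scale`` multiplies the nominal density of
    the assigned material; it applies identically to electronic and nuclear
    processes.
    """

    material_index: np.ndarray  # int, shape (nx, ny, nz)
    density_scale: np.ndarray   # float, same shape, > 0
    spacing: tuple[float, float, float]  # mm
    materials: list[Material]

    def __post_init__(self) -> None:
        self.material_index = np.asarray(self.material_index, dtype=np.int32)
        self.density_scale = np.asarray(self.density_scale, dtype=float)
        if self.material_index.shape != self.density_scale.shape:
            raise ValueError("material_index and density_scale shapes differ")
        if self.material_index.min() < 0 or \
                self.material_index.max() >= len(self.materials):
            raise ValueError("voxel references undefined material")
        if not np.all(self.density_scale > 0):
            raise ValueError("density_scale must be > 0 everywhere")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_index.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def density_grid(self) -> np.ndarray:
        """Per-voxel physical density in g/cm^3."""
        nominal = np.array([m.density for m in self.materials])
        return nominal[self.material_index] * self.density_scale


def phantom_from_hu(
    hu_grid: np.ndarray,
    spacing: tuple[float, float, float],
    calibration: HUCalibration | None = None,
) -> VoxelPhantom:
    """Segment a HU grid into a voxel phantom using a calibration table."""
    if calibration is None:
        calibration = build_default_calibration()
    hu_grid = np.asarray(hu_grid, dtype=float)
    if not np.all(np.isfinite(hu_grid)):
        bad = np.argwhere(~np.isfinite(hu_grid))
        raise ValueError(
            f"non-finite HU at voxel indices {bad[:10].tolist()}"
            + ("..." if len(bad) > 10 else "")
        )
    ids = calibration.material_ids()
    materials = [calibration.materials[i] for i in ids]
    id_to_idx = {name: k for k, name in enumerate(ids)}

    hu = np.clip(hu_grid, calibration.hu_min, calibration.hu_max)
    if np.any(hu != hu_grid):
        log.warning("clamped %d HU values to calibration bounds",
                    int(np.sum(hu != hu_grid)))
    lows = np.array([s.hu_low for s in calibration.segments])
    seg_idx = np.clip(np.searchsorted(lows, hu, side="right") - 1,
                      0, len(lows) - 1)
    seg_mat = np.array([id_to_idx[s.material_id]
                        for s in calibration.segments])
    centers = np.array([s.center for s in calibration.segments])
    nominal = np.array([s.nominal_density for s in calibration.segments])
    slopes = np.array([s.density_slope for s in calibration.segments])

    mat_index = seg_mat[seg_idx]
    dens = nominal[seg_idx] + slopes[seg_idx] * (hu - centers[seg_idx])
    mat_nominal = np.array([m.density for m in materials])
    scale = np.maximum(dens, 1e-6) / mat_nominal[mat_index]
    # compact to the materials actually present so downstream per-material
    # caches (stopping tables, radiation lengths) stay small
    used = np.unique(mat_index)
    remap = np.full(len(materials), -1, dtype=np.int32)
    remap[used] = np.arange(len(used))
    return VoxelPhantom(remap[mat_index], scale, tuple(spacing),
                        [materials[u] for u in used])


def make_slab_phantom(
    layers: Sequence[tuple[str | Material, float]],
    cross_section_mm: float = 40.0,
    spacing_mm: float | tuple[float, float, float] = 1.0,
) -> VoxelPhantom:
    """Layered phantom along the beam (+z) axis.

    ``layers`` is a list of ``(material, thickness_mm)``; thicknesses are
    rounded to whole voxels (at least one voxel per layer).
    """
    if isinstance(spacing_mm, (int, float)):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    mats: list[Material] = []
    slabs: list[tuple[int, int]] = []
    for entry, thick in layers:
        if thick <= 0:
            raise ValueError("layer thickness must be > 0")
        if isinstance(entry, str):
            if entry not in BUILTIN_MATERIALS:
                raise KeyError(
                    f"unknown material {entry!r}; built-ins: "
                    f"{sorted(BUILTIN_MATERIALS)}"
                )
            entry = BUILTIN_MATERIALS[entry]
        if entry not in mats:
            mats.append(entry)
        nz = max(1, round(thick / spacing[2]))
        slabs.append((mats.index(entry), nz))
    nz_total = sum(n for _, n in slabs)
    nt = max(1, round(cross_section_mm / spacing[0]))
    mat_index = np.zeros((nt, nt, nz_total), dtype=np.int32)
    z0 = 0
    for mi, n in slabs:
        mat_index[:, :, z0:z0 + n] = mi
        z0 += n
    return VoxelPhantom(mat_index, np.ones_like(mat_index, dtype=float),
                        spacing, mats)
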