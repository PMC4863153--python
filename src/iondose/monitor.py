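"""In-vivo range-verification surrogates: beta+ emitters and PET scoring.

Therapeutic beams activate tissue nuclei; the dominant reactions for
proton PET monitoring are 16O(p,x)15O and 12C(p,x)11C.  Production maps
are obtained by folding the simulated primary fluence spectra with
reaction cross sections and target-nuclide densities.  A parameterized
ring detector scores annihilation-photon coincidences (geometric
acceptance, energy window with sqrt(E)-scaled Gaussian resolution, time
window, per-module dead time) which are binned into (radial offset,
azimuth) sinograms.  Prompt-signal depth profiles with a low-energy
threshold and detector-resolution convolution complete the monitoring
toolbox.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import VoxelPhantom
from .transport import DoseGrid

log = logging.getLogger(__name__)

LN2 = math.log(2.0)
E_ANNIHILATION_KEV = 511.0

#: Half-lives (s) of the common therapy-produced beta+ emitters.
HALF_LIVES_S = {"C11": 1220.04, "N13": 597.9, "O15": 122.24, "C10": 19.3}


@dataclass
class CrossSectionTable:
    """sigma(E) for one production reaction, e.g. ``16O(p,x)15O``."""

    reaction: str
    product: str            # isotope key into HALF_LIVES_S (or custom)
    half_life_s: float
    target_z: int           # Z of the target element in tissue
    energy_grid: np.ndarray  # MeV (per nucleon for ion beams)
    sigma_mb: np.ndarray

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.sigma_mb = np.asarray(self.sigma_mb, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.sigma_mb < 0):
            raise ValueError("cross sections must be >= 0")

    def sigma_at(self, E) -> np.ndarray:
        """sigma in mb; zero below the tabulated threshold."""
        e = np.asarray(E, dtype=float)
        return np.interp(e, self.energy_grid, self.sigma_mb,
                         left=0.0, right=self.sigma_mb[-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"E_MeV": self.energy_grid,
                      "sigma_mb": self.sigma_mb}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reaction: str, product: str, half_life_s: float,
                 target_z: int) -> "CrossSectionTable":
        df = pd.read_csv(path, comment="#")
        return cls(reaction, product, half_life_s, target_z,
                   df["E_MeV"].to_numpy(), df["sigma_mb"].to_numpy())


@dataclass
class EmitterMap:
    """Per-isotope beta+ production density, decays-pending per primary.

    ``per_isotope`` maps isotope -> 3D array on the phantom grid (counts
    per voxel per primary).  Production is placed in beam-reached voxels
    by weighting each depth slice's yield with the dose pattern of that
    slice (a localization surrogate for full 3D fluence scoring).
    """

    phantom: VoxelPhantom
    per_isotope: dict[str, np.ndarray]
    half_lives_s: dict[str, float]

    def total(self, isotope: str | None = None) -> float:
        if isotope is not None:
            return float(self.per_isotope[isotope].sum())
        return float(sum(a.sum() for a in self.per_isotope.values()))

    def depth_profile(self, isotope: str) -> np.ndarray:
        return self.per_isotope[isotope].sum(axis=(0, 1))


def emitter_production(grid: DoseGrid,
                       xs_tables: list[CrossSectionTable]) -> EmitterMap:
    """Fold fluence spectra with cross sections and target densities.

    Per depth slice and isotope: sum over energy bins of
    track-length(E) * sigma(E) * n_target; linear in fluence and sigma.
    """
    phantom = grid.phantom
    e_cents = 0.5 * (grid.fluence_energy_edges[1:]
                     + grid.fluence_energy_edges[:-1])
    rho = phantom.density_grid()
    from .constants import CONSTANTS
    per_iso: dict[str, np.ndarray] = {}
    half_lives: dict[str, float] = {}
    dose3 = grid.edep
    slice_tot = dose3.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        slice_weight = np.where(slice_tot > 0,
                                dose3 / np.maximum(slice_tot, 1e-300), 0.0)
    for xs in xs_tables:
        # per-voxel target nuclide density (nuclei/cm^3)
        n_t = np.zeros(phantom.shape)
        for mi, mat in enumerate(phantom.materials):
            w_frac = sum(w for z, a, w in mat.elements if z == xs.target_z)
            a_mass = next((a for z, a, w in mat.elements
                           if z == xs.target_z), None)
            if w_frac > 0 and a_mass:
                sel = phantom.material_index == mi
                n_t[sel] = (rho[sel] * CONSTANTS.avogadro
                            * w_frac / a_mass)
        if n_t.max() == 0.0:
            log.warning("reaction %s: target Z=%d absent everywhere",
                        xs.reaction, xs.target_z)
        sigma_cm2 = xs.sigma_at(e_cents) * 1e-27
        slice_nt = np.array([
            n_t[:, :, k].max() if n_t[:, :, k].max() > 0 else 0.0
            for k in range(phantom.shape[2])
        ])
        prod_depth = np.zeros(phantom.shape[2])
        for species, flu in grid.fluence_spectra.items():
            prod_depth += (flu @ sigma_cm2) * slice_nt
        prod3 = slice_weight * prod_depth[None, None, :]
        key = xs.product
        per_iso[key] = per_iso.get(key, 0.0) + prod3
        half_lives[key] = xs.half_life_s
    return EmitterMap(phantom, per_iso, half_lives)


def activity_in_window(emap: EmitterMap, t_start: float,
                       t_acq: float) -> dict[str, np.ndarray]:
    """Expected decays per voxel per primary inside the acquisition
    window [t_start, t_start + t_acq]:
    N (exp(-lambda t_start) - exp(-lambda (t_start + t_acq)))."""
    if t_start < 0 or t_acq < 0:
        raise ValueError("times must be >= 0")
    out = {}
    for iso, n_map in emap.per_isotope.items():
        lam = LN2 / emap.half_lives_s[iso]
        frac = math.exp(-lam * t_start) - math.exp(-lam * (t_start + t_acq))
        out[iso] = n_map * frac
    return out


def decay_fraction(half_life_s: float, t_start: float, t_acq: float,
                   washout_rate: float = 0.0) -> float:
    """Closed-form fraction of produced nuclei decaying in the window;
    an optional uniform metabolic washout rate (1/s) adds to lambda."""
    lam = LN2 / half_life_s + washout_rate
    return math.exp(-lam * t_start) - math.exp(-lam * (t_start + t_acq))


# -- ring detector ----------------------------------------------------------

@dataclass(frozen=True)
class RingDetector:
    """Cylindrical coincidence detector parameterization.

    ``opening_angle`` (degrees, 0..180) sets the azimuthal coverage: the
    crystals occupy two opposed arcs each spanning 2*opening_angle, so
    180 degrees closes the complete ring and 0 removes all detectors.
    """

    radius: float               # mm
    axial_extent: float         # mm
    n_modules: int = 64
    opening_angle: float = 180.0  # degrees
    energy_window: tuple[float, float] = (350.0, 650.0)  # keV
    energy_resolution_fwhm_frac_at_ref: float = 0.07
    reference_energy_kev: float = 662.0
    resolution_sqrt_scaling: bool = True
    time_resolution_ns: float = 2.0
    dead_time_ns: float = 0.0
    min_scoring_time_s: float = 0.0
    acollinearity_fwhm_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 0.0 <= self.opening_angle <= 180.0:
            raise ValueError("opening_angle must lie in [0, 180] degrees")
        lo, hi = self.energy_window
        if not lo < hi:
            raise ValueError("energy window must satisfy E_low < E_high")

    def fwhm_at(self, e_kev: float) -> float:
        f = self.energy_resolution_fwhm_frac_at_ref
        if self.resolution_sqrt_scaling:
            return f * math.sqrt(e_kev * self.reference_energy_kev)
        return f * e_kev

    def covers_azimuth(self, phi: np.ndarray) -> np.ndarray:
        """Whether azimuth (radians) falls on a detector arc."""
        half = math.radians(self.opening_angle)
        if half <= 0:
            return np.zeros_like(phi, dtype=bool)
        p = np.mod(phi, 2.0 * math.pi)
        d0 = np.minimum(p, 2.0 * math.pi - p)              # dist to phi=0
        d180 = np.abs(p - math.pi)                          # dist to phi=pi
        return (d0 <= half) | (d180 <= half)

    def module_of(self, phi: np.ndarray) -> np.ndarray:
        p = np.mod(phi, 2.0 * math.pi)
        return (p / (2.0 * math.pi) * self.n_modules).astype(int) \
            % self.n_modules


@dataclass
class CoincidenceEvent:
    time_s: float
    p1: np.ndarray  # (x, y, z) mm on the ring
    p2: np.ndarray
    e1_kev: float
    e2_kev: float


def detect_coincidences(
    decay_positions: np.ndarray,      # (n, 3) mm
    decay_times: np.ndarray,          # (n,) s
    detector: RingDetector,
    rng: np.random.Generator,
) -> list[CoincidenceEvent]:
    """Simulate back-to-back 511 keV photon pairs and apply the full
    acceptance chain: geometry (ring radius, axial extent, opening
    angle), smeared energies inside the window, arrival-time difference
    within the time resolution, minimum scoring time and module dead
    time."""
    pos = np.atleast_2d(np.asarray(decay_positions, dtype=float))
    times = np.atleast_1d(np.asarray(decay_times, dtype=float))
    n = len(pos)
    # isotropic emission direction; photon 2 back-to-back (plus optional
    # Gaussian acollinearity jitter on photon 2)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u2 = -u
    if detector.acollinearity_fwhm_deg > 0:
        sigma = math.radians(detector.acollinearity_fwhm_deg) / 2.3548
        jitter = rng.normal(0.0, sigma, size=(n, 3))
        u2 = u2 + jitter
        u2 /= np.linalg.norm(u2, axis=1, keepdims=True)

    events: list[CoincidenceEvent] = []
    module_busy_until: dict[int, float] = {}
    order = np.argsort(times)
    c_mm_per_ns = 299.792458
    for i in order:
        if times[i] < detector.min_scoring_time_s:
            continue
        hits = []
        for d in (u[i], u2[i]):
            hit = _cylinder_hit(pos[i], d, detector.radius)
            if hit is None:
                break
            if abs(hit[2]) > detector.axial_extent / 2.0:
                break
            phi = math.atan2(hit[1], hit[0])
            if not detector.covers_azimuth(np.array([phi]))[0]:
                break
            flight_mm = float(np.linalg.norm(hit - pos[i]))
            hits.append((hit, phi, flight_mm / c_mm_per_ns))
        if len(hits) != 2:
            continue
        dt_ns = abs(hits[0][2] - hits[1][2])
        if dt_ns > detector.time_resolution_ns:
            continue
        e_smear = []
        for _ in range(2):
            fwhm = detector.fwhm_at(E_ANNIHILATION_KEV)
            e = E_ANNIHILATION_KEV + (
                rng.normal(0.0, fwhm / 2.3548) if fwhm > 0 else 0.0)
            e_smear.append(e)
        lo, hi = detector.energy_window
        if not (lo <= e_smear[0] <= hi and lo <= e_smear[1] <= hi):
            continue
        if detector.dead_time_ns > 0:
            t_ns = times[i] * 1e9
            mods = [int(detector.module_of(np.array([h[1]]))[0])
                    for h in hits]
            if any(module_busy_until.get(mm, -math.inf) > t_ns
                   for mm in mods):
                continue
            for mm in mods:
                module_busy_until[mm] = t_ns + detector.dead_time_ns
        events.append(CoincidenceEvent(
            float(times[i]), hits[0][0], hits[1][0],
            e_smear[0], e_smear[1]))
    return events


def _cylinder_hit(origin: np.ndarray, direction: np.ndarray,
                  radius: float) -> np.ndarray | None:
    """First intersection of the ray with the infinite cylinder
    x^2 + y^2 = R^2 (ring axis along z)."""
    ox, oy = origin[0], origin[1]
    dx, dy = direction[0], direction[1]
    a = dx * dx + dy * dy
    if a < 1e-300:
        return None
    b = 2.0 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - radius * radius
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return None
    t = (-b + math.sqrt(disc)) / (2.0 * a)
    if t <= 0:
        return None
    return origin + t * direction


def geometric_acceptance_center(detector: RingDetector) -> float:
    """Analytic pair-acceptance for a decay at the ring center of a full
    ring: both photons hit iff |cos(polar)| < sin(atan(half-length /
    radius)); equals the axial solid-angle fraction of one photon."""
    half = detector.axial_extent / 2.0
    cos_max = half / math.hypot(half, detector.radius)
    return cos_max  # fraction of isotropic pairs with both hits axial


# -- sinogram ---------------------------------------------------------------

@dataclass
class Sinogram:
    counts: np.ndarray       # (n_radial, n_angular) integer counts
    radial_edges: np.ndarray  # mm
    angular_edges: np.ndarray  # radians over [0, pi)
    overflow: int = 0

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum()) + self.overflow


def bin_sinogram(events: list[CoincidenceEvent], n_radial: int = 64,
                 n_angular: int = 90,
                 radial_max: float | None = None) -> Sinogram:
    """Bin each line of response into (signed radial offset s, azimuth
    phi) of its transaxial projection; counts are conserved (out-of-range
    LORs go to the overflow tally)."""
    if radial_max is None:
        radial_max = max((float(np.linalg.norm(e.p1[:2])) for e in events),
                         default=1.0)
    r_edges = np.linspace(-radial_max, radial_max, n_radial + 1)
    a_edges = np.linspace(0.0, math.pi, n_angular + 1)
    counts = np.zeros((n_radial, n_angular), dtype=int)
    overflow = 0
    for e in events:
        dx = e.p2[0] - e.p1[0]
        dy = e.p2[1] - e.p1[1]
        norm = math.hypot(dx, dy)
        if norm < 1e-12:
            overflow += 1
            continue
        ux, uy = dx / norm, dy / norm
        # canonical orientation (direction in the upper half-plane) so the
        # signed offset does not depend on which photon is labelled first
        if uy < 0.0 or (uy == 0.0 and ux < 0.0):
            ux, uy = -ux, -uy
        phi = math.atan2(uy, ux) % math.pi
        s = e.p1[0] * uy - e.p1[1] * ux  # signed distance of LOR to origin
        ir = np.searchsorted(r_edges, s) - 1
        ia = min(np.searchsorted(a_edges, phi) - 1, n_angular - 1)
        if 0 <= ir < n_radial and 0 <= ia < n_angular:
            counts[ir, ia] += 1
        else:
            overflow += 1
    return Sinogram(counts, r_edges, a_edges, overflow)


# -- spectra and prompt profiles -------------------------------------------

def convolve_energy_resolution(
    energy_edges: np.ndarray, spectrum: np.ndarray,
    detector: RingDetector,
) -> np.ndarray:
    """Convolve a binned spectrum with the Gaussian detector response
    whose FWHM is ``frac * E_ref`` at the reference energy and scales as
    sqrt(E); the spectrum integral is preserved to 1e-9."""
    edges = np.asarray(energy_edges, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    cents = 0.5 * (edges[1:] + edges[:-1])
    out = np.zeros_like(spec)
    for j, (e0, s) in enumerate(zip(cents, spec)):
        if s == 0.0:
            continue
        fwhm = detector.fwhm_at(e0)
        if fwhm <= 0:
            out[j] += s
            continue
        sigma = fwhm / 2.3548200450309493
        from scipy.stats import norm
        cdf = norm.cdf(edges, loc=e0, scale=sigma)
        kernel = np.diff(cdf)
        ksum = kernel.sum()
        if ksum <= 0:
            out[j] += s
            continue
        out += s * kernel / ksum  # renormalized: integral preserved
    return out


def prompt_depth_profile(
    depths_mm: np.ndarray, photon_energies_mev: np.ndarray,
    energy_threshold_mev: float, depth_edges_mm: np.ndarray,
    weights: np.ndarray | None = None,
    background_offset: float = 0.0,
) -> np.ndarray:
    """Histogram over depth of photons above the low-energy threshold
    (2 MeV is the conventional gate), per primary, with an optional
    constant background offset subtracted (clipped at zero)."""
    d = np.asarray(depths_mm, dtype=float)
    e = np.asarray(photon_energies_mev, dtype=float)
    w = np.ones_like(d) if weights is None else np.asarray(weights)
    keep = e >= energy_threshold_mev
    hist, _ = np.histogram(d[keep], bins=depth_edges_mm,
                           weights=w[keep])
    return np.maximum(hist - background_offset, 0.0)
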