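"""Condensed-history Monte Carlo transport through a voxel phantom.

Primaries are advanced in vectorized lockstep: every step is capped both by
a maximum fractional energy loss and by the chord to the next voxel face,
the mean energy loss comes from the stopping-power table, Gaussian (Bohr)
straggling and Highland multiple-scattering deflections are sampled per
step, and nuclear removal follows an exponential attenuation law with a
parameterized forward fragment-tail surrogate replacing explicit fragment
transport.  Every MeV of beam energy is accounted to exactly one of
{deposited, escaped, tail-escaped}; the ledger is checked in tests.

Primaries are split into batches with independent counter-based
(Philox) substreams, giving reproducible runs and a batch-variance
estimate of the statistical uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .constants import CONSTANTS
from .materials import Material, VoxelPhantom, WATER_I_DEFAULT_EV
from .stopping import (DEFAULT_OPTIONS, ProjectileSpec, StoppingOptions,
                       StoppingTable, kinematics_from_energy,
                       surrogate_models)

log = logging.getLogger(__name__)

#: Bohr straggling constant 4 pi r_e^2 (m_e c^2)^2 N_Av in MeV^2 cm^2/g
#: (multiplies z_eff^2 (Z/A) rho dx).
BOHR_CONST = 0.1569


# -- beam / config ----------------------------------------------------------

@dataclass(frozen=True)
class BeamSpec:
    """Pencil-beam source: Gaussian spot and energy spread, fixed
    direction, nominal energy in MeV/u (energy before the phantom)."""

    projectile: ProjectileSpec
    nominal_energy: float           # MeV/u
    n_primaries: int
    energy_sigma: float = 0.0       # MeV/u
    spot_sigma_x: float = 0.0       # mm
    spot_sigma_y: float = 0.0       # mm
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.nominal_energy <= 0:
            raise ValueError("nominal_energy must be > 0")
        if self.n_primaries < 1:
            raise ValueError("n_primaries must be >= 1")
        if self.energy_sigma < 0 or self.spot_sigma_x < 0 \
                or self.spot_sigma_y < 0:
            raise ValueError("sigmas must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("direction must be normalized to 1e-12")


TailParams = tuple[float, float, float]  # (local_fraction, tail_mfp_cm,
#                                           forward_dose_fraction)


@dataclass(frozen=True)
class TransportConfig:
    """All transport knobs: step control, physics toggles, seeds."""

    max_fractional_energy_loss_per_step: float = 0.02
    delta_threshold: float = 0.1    # MeV (>= 1 keV)
    straggling_model: Literal["none", "gaussian"] = "gaussian"
    mcs_model: Literal["none", "highland"] = "highland"
    nuclear_model: Literal["none", "attenuation",
                           "attenuation+tail"] = "attenuation+tail"
    tail_params: TailParams = (0.6, 2.0, 0.3)
    rng_seed: int = 0
    n_batches: int = 10
    energy_cutoff: float = 0.25     # MeV/u; residual deposited locally
    stopping_options: StoppingOptions = DEFAULT_OPTIONS
    fluence_bins: int = 64
    score_fluence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.max_fractional_energy_loss_per_step <= 0.05:
            raise ValueError("max fractional energy loss must be in (0, 0.05]")
        if self.delta_threshold < 1e-3:
            raise ValueError("delta_threshold must be >= 1 keV")
        local, mfp, forward = self.tail_params
        if not (0 <= local <= 1 and 0 <= forward <= 1
                and local + forward <= 1 and mfp > 0):
            raise ValueError("invalid fragment-tail parameters")


@dataclass
class EnergyLedger:
    """Per-run energy bookkeeping (MeV, all primaries)."""

    beam_energy: float = 0.0
    deposited: float = 0.0
    escaped: float = 0.0       # left the phantom / removed unaccounted
    tail_escaped: float = 0.0  # fragment-tail budget beyond the phantom

    @property
    def closure(self) -> float:
        """Relative imbalance; 0 for a perfectly closed ledger."""
        out = self.deposited + self.escaped + self.tail_escaped
        return abs(out - self.beam_energy) / max(self.beam_energy, 1e-30)


@dataclass
class DepthDoseCurve:
    """Laterally integrated depth dose, MeV cm^2/g per primary."""

    depth_centers: np.ndarray   # mm
    dose: np.ndarray
    statistical_sigma: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.depth_centers) == len(self.dose)
                == len(self.statistical_sigma)):
            raise ValueError("array lengths differ")
        if np.any(np.diff(self.depth_centers) <= 0):
            raise ValueError("depths must be strictly increasing")

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"depth_mm": self.depth_centers, "dose": self.dose,
                      "sigma": self.statistical_sigma}).to_csv(path,
                                                               index=False)

    @classmethod
    def from_csv(cls, path) -> "DepthDoseCurve":
        import pandas as pd
        df = pd.read_csv(path, comment="#")
        sigma = df["sigma"].to_numpy() if "sigma" in df \
            else np.zeros(len(df))
        return cls(df["depth_mm"].to_numpy(), df["dose"].to_numpy(), sigma)


@dataclass
class DoseGrid:
    """Scored output of one simulation.

    ``edep`` is total deposited energy (MeV) per voxel over all primaries;
    ``dose`` converts to MeV/g per primary.  ``fluence_spectra`` holds the
    depth-binned primary track-length spectra (cm of track per energy bin
    per depth slice, per primary) needed by the mixed-field biology and the
    emitter-production scoring.
    """

    phantom: VoxelPhantom
    edep: np.ndarray
    n_primaries: int
    ledger: EnergyLedger
    batch_depth_dose: np.ndarray            # (n_batches, nz)
    fluence_spectra: dict[str, np.ndarray]  # species -> (nz, nE)
    fluence_energy_edges: np.ndarray
    plane_crossings: np.ndarray             # primaries crossing plane k
    beam: BeamSpec
    config: TransportConfig
    sum_edep_alpha: np.ndarray | None = None  # MeV * Gy^-1 weighted sums
    sum_edep_beta: np.ndarray | None = None

    @property
    def dose(self) -> np.ndarray:
        """Per-voxel dose in MeV/g per primary."""
        vol = np.prod([s / 10.0 for s in self.phantom.spacing])  # cm^3
        mass = self.phantom.density_grid() * vol
        return self.edep / np.maximum(mass, 1e-30) / self.n_primaries


# -- nuclear attenuation surrogate -----------------------------------------

_R0_FM = 1.35
_FM2_TO_MB = 10.0


def bradt_peters_sigma_mb(a_proj: int, a_target: float) -> float:
    """Geometric (Bradt-Peters) inelastic cross section in mb."""
    term = a_proj ** (1.0 / 3.0) + a_target ** (1.0 / 3.0) - 1.0
    return math.pi * _R0_FM**2 * term**2 * _FM2_TO_MB


def inelastic_sigma_mb(a_proj: int, a_target: float,
                       E: np.ndarray) -> np.ndarray:
    """Smooth surrogate sigma(E): zero below an 8 MeV/u threshold, rising
    to the geometric plateau with a 15 MeV/u rise scale."""
    e = np.asarray(E, dtype=float)
    shape = np.where(e > 8.0, 1.0 - np.exp(-(e - 8.0) / 15.0), 0.0)
    return bradt_peters_sigma_mb(a_proj, a_target) * shape


def nuclear_mean_free_path(
    projectile: ProjectileSpec, E: float | np.ndarray, material: Material,
    sigma_tables: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Nuclear mean free path lambda = 1/sum_i n_i sigma_i(E) in cm.

    ``sigma_tables`` optionally maps target Z to (E_grid MeV/u, sigma mb);
    elements absent from the mapping raise a KeyError naming the pair.
    Without tables the packaged Bradt-Peters surrogate is used.
    """
    e = np.atleast_1d(np.asarray(E, dtype=float))
    inv = np.zeros_like(e)
    for z, a, w in material.elements:
        n_i = material.density * CONSTANTS.avogadro * w / a  # nuclei/cm^3
        if sigma_tables is not None:
            if z not in sigma_tables:
                raise KeyError(
                    f"no cross-section table for projectile "
                    f"{projectile.name!r} on target Z={z}"
                )
            e_grid, sig = sigma_tables[z]
            sigma = np.interp(e, e_grid, sig)
        else:
            sigma = inelastic_sigma_mb(projectile.mass_number, a, e)
        inv += n_i * sigma * 1e-27  # mb -> cm^2
    lam = np.where(inv > 0, 1.0 / np.maximum(inv, 1e-300), np.inf)
    return lam if np.ndim(E) else float(lam[0])


# -- step control -----------------------------------------------------------

def choose_step(
    E: float, material: Material, projectile: ProjectileSpec,
    config: TransportConfig, remaining_chord_cm: float = math.inf,
    density_scale: float = 1.0,
) -> float:
    """Scalar reference implementation of the per-step length rule (cm):
    min(energy-cap step, remaining voxel chord)."""
    if E <= 0:
        raise ValueError("energy must be > 0")
    rho = material.density * density_scale
    if rho < 1e-12:
        return max(remaining_chord_cm, 1e-6)  # vacuum drift
    table = _get_table(projectile, material, config.stopping_options)
    s_lin = float(table.stopping_at(np.array([E]))[0]) * rho
    step = config.max_fractional_energy_loss_per_step \
        * (E * projectile.mass_number) / s_lin
    return max(min(step, remaining_chord_cm), 1e-6)


_TABLE_CACHE: dict[tuple, StoppingTable] = {}


def _get_table(projectile: ProjectileSpec, material: Material,
               options: StoppingOptions) -> StoppingTable:
    key = (projectile.name, material.name, material.density,
           material.mean_excitation_energy, options)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = StoppingTable.build(projectile, material,
                                                options=options)
    return _TABLE_CACHE[key]


def _effective_charge_vec(projectile: ProjectileSpec, beta: np.ndarray,
                          options: StoppingOptions) -> np.ndarray:
    z = projectile.charge_number
    if z <= 2:
        return np.full_like(beta, float(z))
    k = options.effective_charge_k
    return z * (1.0 - np.exp(-k * beta * z ** (-2.0 / 3.0)))


def sample_energy_loss(
    mean_loss: float, E: float, projectile: ProjectileSpec,
    material: Material, step_cm: float, config: TransportConfig,
    rng: np.random.Generator, size: int | None = None,
):
    """Reference sampler: Gaussian about the mean with the Bohr variance,
    truncated to [0, total kinetic energy].  ``size`` draws a vector."""
    if mean_loss < 0:
        raise ValueError("mean_loss must be >= 0")
    e_total = E * projectile.mass_number
    if config.straggling_model == "none":
        val = min(mean_loss, e_total)
        return val if size is None else np.full(size, val)
    state = kinematics_from_energy(E, projectile)
    zeff = float(_effective_charge_vec(projectile,
                                       np.array([state.beta]),
                                       config.stopping_options)[0])
    var = bohr_variance(zeff, material.z_over_a, material.density, step_cm,
                        state.beta)
    draw = rng.normal(mean_loss, math.sqrt(var), size=size)
    clipped = np.clip(draw, 0.0, e_total)
    return float(clipped) if size is None else clipped


def bohr_variance(zeff, z_over_a, rho, step_cm, beta):
    """Bohr energy-loss straggling variance (MeV^2):
    0.1569 z_eff^2 (Z/A) rho dx (1 - beta^2/2)/(1 - beta^2)."""
    b2 = beta**2
    return (BOHR_CONST * zeff**2 * z_over_a * rho * step_cm
            * (1.0 - b2 / 2.0) / (1.0 - b2))


# -- multiple Coulomb scattering -------------------------------------------

def radiation_length(material: Material) -> float:
    """Mass radiation length X0 (g/cm^2) from the PDG-style per-element
    formula combined by mass fractions."""
    inv = 0.0
    for z, a, w in material.elements:
        x0_el = 716.408 * a / (z * (z + 1.0)
                               * math.log(287.0 / math.sqrt(z)))
        inv += w / x0_el
    return 1.0 / inv


def highland_theta0(
    E: float | np.ndarray, projectile: ProjectileSpec, t_over_x0
) -> np.ndarray:
    """Highland characteristic angle (radians) for mass thickness fraction
    ``t_over_x0``; zero where t/X0 <= 0."""
    e = np.asarray(E, dtype=float)
    gamma = 1.0 + e * projectile.mass_number / projectile.mass
    beta = np.sqrt(1.0 - 1.0 / gamma**2)
    pc = projectile.mass * beta * gamma
    t = np.asarray(t_over_x0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = (13.6 / (beta * pc) * projectile.charge_number
                 * np.sqrt(np.maximum(t, 0.0))
                 * (1.0 + 0.038 * np.log(np.maximum(t, 1e-300))))
    return np.where(t > 0, np.maximum(theta, 0.0), 0.0)


def sample_mcs_deflection(
    E: float, projectile: ProjectileSpec, step_cm: float,
    material: Material, config: TransportConfig, rng: np.random.Generator,
    size: int | None = None,
):
    """Reference sampler for the Gaussian Highland deflection; returns
    (theta_x, theta_y) scalars or arrays of shape (size,)."""
    if step_cm < 0:
        raise ValueError("step must be >= 0")
    n = 1 if size is None else size
    if config.mcs_model == "none" or step_cm == 0.0:
        tx = ty = np.zeros(n)
    else:
        t_over_x0 = step_cm * material.density / radiation_length(material)
        theta0 = float(highland_theta0(E, projectile, t_over_x0))
        if theta0 <= 0:
            tx = ty = np.zeros(n)
        else:
            tx = rng.normal(0.0, theta0, n)
            ty = rng.normal(0.0, theta0, n)
    if size is None:
        return float(tx[0]), float(ty[0])
    return tx, ty


# -- main loop --------------------------------------------------------------

def run_simulation(
    beam: BeamSpec,
    phantom: VoxelPhantom,
    config: TransportConfig,
    lq_table=None,
) -> DoseGrid:
    """Transport ``beam.n_primaries`` histories and score dose (and
    optionally dose-weighted LQ coefficient sums when ``lq_table``
    provides ``alpha_at(E)``/``beta_at(E)``).

    Identical (seed, config, inputs) give bit-identical grids.
    """
    _log_run_header(beam, phantom, config)
    shape = phantom.shape
    nz = shape[2]
    edep = np.zeros(shape)
    sum_ea = np.zeros(shape) if lq_table is not None else None
    sum_eb = np.zeros(shape) if lq_table is not None else None
    e_edges = np.linspace(
        0.0, beam.nominal_energy * 1.05 + 5.0 * beam.energy_sigma,
        config.fluence_bins + 1,
    )
    flu = np.zeros((nz, config.fluence_bins)) if config.score_fluence \
        else None
    crossings_diff = np.zeros(nz + 2)
    ledger = EnergyLedger()

    n_b = min(config.n_batches, beam.n_primaries)
    counts = [len(c) for c in np.array_split(np.arange(beam.n_primaries),
                                             n_b)]
    batch_dd = np.zeros((n_b, nz))
    rho_grid = phantom.density_grid()
    h_z_cm = phantom.spacing[2] / 10.0
    slice_mass_per_area = rho_grid.mean(axis=(0, 1)) * h_z_cm  # g/cm^2

    for b, n in enumerate(counts):
        rng = np.random.Generator(np.random.Philox(
            key=np.uint64(config.rng_seed * 65536 + b)))
        b_edep = np.zeros(shape)
        _transport_batch(beam, phantom, config, n, rng, b_edep, sum_ea,
                         sum_eb, flu, e_edges, crossings_diff, ledger,
                         lq_table)
        edep += b_edep
        batch_dd[b] = b_edep.sum(axis=(0, 1)) / n / slice_mass_per_area

    if ledger.beam_energy == 0.0:
        log.warning("beam deposited no energy in the phantom")
    crossings = np.cumsum(crossings_diff)[:nz + 1]
    spectra = {}
    if flu is not None:
        spectra[beam.projectile.name] = flu / beam.n_primaries
    return DoseGrid(
        phantom=phantom, edep=edep, n_primaries=beam.n_primaries,
        ledger=ledger, batch_depth_dose=batch_dd,
        fluence_spectra=spectra, fluence_energy_edges=e_edges,
        plane_crossings=crossings, beam=beam, config=config,
        sum_edep_alpha=sum_ea, sum_edep_beta=sum_eb,
    )


def _log_run_header(beam: BeamSpec, phantom: VoxelPhantom,
                    config: TransportConfig) -> None:
    i_values = {m.name: m.mean_excitation_energy for m in phantom.materials}
    log.info(
        "run header: projectile=%s E=%.4g MeV/u n=%d seed=%d | "
        "straggling=%s mcs=%s nuclear=%s tail=%s | I[eV]=%s "
        "(water default %g eV) | surrogates=%s",
        beam.projectile.name, beam.nominal_energy, beam.n_primaries,
        config.rng_seed, config.straggling_model, config.mcs_model,
        config.nuclear_model, config.tail_params, i_values,
        WATER_I_DEFAULT_EV, sorted(surrogate_models()),
    )


def _transport_batch(beam, phantom, config, n, rng, edep, sum_ea, sum_eb,
                     flu, e_edges, crossings_diff, ledger, lq_table):
    proj = beam.projectile
    a_p = proj.mass_number
    shape = phantom.shape
    h = np.array(phantom.spacing) / 10.0  # cm
    extent = np.array(shape) * h
    mat_idx_grid = phantom.material_index
    scale_grid = phantom.density_scale
    rho_nom = np.array([m.density for m in phantom.materials])
    z_over_a = np.array([m.z_over_a for m in phantom.materials])
    x0_mass = np.array([radiation_length(m) for m in phantom.materials])
    tables = [_get_table(proj, m, config.stopping_options)
              for m in phantom.materials]
    # nuclear inverse mfp per material on a shared log grid
    e_grid = np.geomspace(0.25, max(beam.nominal_energy * 1.2, 1.0), 200)
    inv_mfp = np.array([
        1.0 / nuclear_mean_free_path(proj, e_grid, m)
        for m in phantom.materials
    ])
    nuclear_on = config.nuclear_model != "none"
    tail_on = config.nuclear_model == "attenuation+tail"
    local_frac, tail_mfp, forward_frac = config.tail_params
    if not tail_on:
        local_frac, forward_frac = 1.0, 0.0  # pure attenuation: deposit all
    f_max = config.max_fractional_energy_loss_per_step
    e_cut_total = config.energy_cutoff * a_p

    # ---- source sampling
    pos = np.tile(np.asarray(beam.position, dtype=float) / 10.0, (n, 1))
    pos[:, 0] += rng.normal(0.0, beam.spot_sigma_x / 10.0, n) \
        if beam.spot_sigma_x > 0 else 0.0
    pos[:, 1] += rng.normal(0.0, beam.spot_sigma_y / 10.0, n) \
        if beam.spot_sigma_y > 0 else 0.0
    dirs = np.tile(np.asarray(beam.direction, dtype=float), (n, 1))
    e_u = np.full(n, beam.nominal_energy)
    if beam.energy_sigma > 0:
        e_u = np.maximum(rng.normal(beam.nominal_energy, beam.energy_sigma,
                                    n), 2 * config.energy_cutoff)
    e_tot = e_u * a_p
    ledger.beam_energy += float(e_tot.sum())

    # advance particles outside the phantom to its bounding box
    pos, dirs, e_tot, missed = _project_to_box(pos, dirs, e_tot, extent)
    ledger.escaped += float(missed)
    if len(pos) == 0:
        log.warning("beam missed the phantom entirely; zero dose grid")
        return

    flat_strides = np.array([shape[1] * shape[2], shape[2], 1])
    max_iter = 200000
    for _ in range(max_iter):
        if len(pos) == 0:
            break
        ivox = np.floor(pos / h).astype(np.int64)
        inside = np.all((ivox >= 0) & (ivox < np.array(shape)), axis=1)
        if not inside.all():
            ledger.escaped += float(e_tot[~inside].sum())
            pos, dirs, e_tot, ivox = (a[inside] for a in
                                      (pos, dirs, e_tot, ivox))
            if len(pos) == 0:
                break
        flat = ivox @ flat_strides
        m = mat_idx_grid.reshape(-1)[flat]
        scale = scale_grid.reshape(-1)[flat]
        rho = rho_nom[m] * scale

        e_u = e_tot / a_p
        s_mass = np.empty_like(e_tot)
        for mi in np.unique(m):
            sel = m == mi
            s_mass[sel] = tables[mi].stopping_at(e_u[sel])
        s_lin = s_mass * rho
        vacuum = rho < 1e-12

        # chord to the next voxel face along the direction
        with np.errstate(divide="ignore", invalid="ignore"):
            t_axis = np.where(
                dirs > 0, ((ivox + 1) * h - pos) / dirs,
                np.where(dirs < 0, (ivox * h - pos) / dirs, np.inf),
            )
        chord = np.maximum(t_axis.min(axis=1), 0.0) + 1e-6
        step_e = np.where(vacuum, np.inf, f_max * e_tot
                          / np.maximum(s_lin, 1e-300))
        step = np.maximum(np.minimum(step_e, chord), 1e-6)

        mean_loss = np.where(vacuum, 0.0, s_lin * step)
        gamma = 1.0 + e_u / proj.mass * a_p
        beta = np.sqrt(1.0 - 1.0 / gamma**2)
        if config.straggling_model == "gaussian":
            zeff = _effective_charge_vec(proj, beta,
                                         config.stopping_options)
            var = bohr_variance(zeff, z_over_a[m], rho, step, beta)
            loss = np.clip(rng.normal(mean_loss, np.sqrt(var)), 0.0, e_tot)
        else:
            loss = np.minimum(mean_loss, e_tot)

        e_new = e_tot - loss
        ranged_out = e_new <= e_cut_total
        loss = np.where(ranged_out, e_tot, loss)
        e_new = np.where(ranged_out, 0.0, e_new)

        np.add.at(edep.reshape(-1), flat, loss)
        ledger.deposited += float(loss.sum())
        if lq_table is not None:
            alpha = lq_table.alpha_at(e_u)
            beta_lq = lq_table.beta_at(e_u)
            np.add.at(sum_ea.reshape(-1), flat, loss * alpha)
            np.add.at(sum_eb.reshape(-1), flat, loss * beta_lq)
        if flu is not None:
            ebin = np.clip(np.searchsorted(e_edges, e_u) - 1, 0,
                           flu.shape[1] - 1)
            np.add.at(flu, (ivox[:, 2], ebin), step)

        # primary plane-crossing tally (forward movers)
        z0, z1 = pos[:, 2], pos[:, 2] + dirs[:, 2] * step
        fwd = z1 > z0
        i0 = np.ceil(z0[fwd] / h[2]).astype(np.int64)
        i1 = np.floor(z1[fwd] / h[2]).astype(np.int64)
        ok = i1 >= i0
        np.add.at(crossings_diff, np.clip(i0[ok], 0, shape[2] + 1), 1.0)
        np.add.at(crossings_diff, np.clip(i1[ok] + 1, 0, shape[2] + 1),
                  -1.0)

        alive = ~ranged_out
        # nuclear removal
        if nuclear_on:
            inv_l = np.empty_like(e_tot)
            for mi in np.unique(m):
                sel = m == mi
                inv_l[sel] = np.interp(e_u[sel], e_grid, inv_mfp[mi])
            inv_l *= scale
            p_int = 1.0 - np.exp(-step * inv_l)
            interact = (rng.random(len(pos)) < p_int) & alive
            if interact.any():
                _apply_nuclear(interact, e_new, flat, ivox, pos, edep,
                               ledger, local_frac, forward_frac, tail_mfp,
                               rho_nom, mat_idx_grid, scale_grid, h, shape,
                               sum_ea, sum_eb, lq_table, e_u)
                alive &= ~interact

        # move, then deflect survivors
        pos = pos + dirs * step[:, None]
        if config.mcs_model == "highland":
            t_x0 = step * rho / x0_mass[m]
            theta0 = highland_theta0(e_u, proj, t_x0)
            dirs = _deflect(dirs, rng.normal(0.0, 1.0, len(pos)) * theta0,
                            rng.normal(0.0, 1.0, len(pos)) * theta0)

        pos, dirs, e_tot = pos[alive], dirs[alive], e_new[alive]
    else:
        raise RuntimeError("transport failed to terminate (step underflow?)")


def _project_to_box(pos, dirs, e_tot, extent):
    """Advance particles outside the bounding box to its entry face;
    returns surviving arrays and the total energy of misses."""
    inside = np.all((pos >= 0) & (pos < extent), axis=1)
    if inside.all():
        return pos, dirs, e_tot, 0.0
    out = ~inside
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (0.0 - pos[out]) / dirs[out]
        t2 = (extent - pos[out]) / dirs[out]
    t_lo = np.nanmax(np.minimum(t1, t2), axis=1)
    t_hi = np.nanmin(np.maximum(t1, t2), axis=1)
    hits = (t_hi > t_lo) & (t_lo > 0)
    missed_energy = float(e_tot[out][~hits].sum())
    pos = pos.copy()
    entry = pos[out][hits] + dirs[out][hits] * (t_lo[hits][:, None] + 1e-6)
    keep = inside.copy()
    idx_out = np.where(out)[0]
    pos[idx_out[hits]] = entry
    keep[idx_out[hits]] = True
    return pos[keep], dirs[keep], e_tot[keep], missed_energy


def _deflect(dirs, tx, ty):
    """Rotate each direction by small angles about two transverse axes."""
    # build an orthonormal frame (e1, e2, d)
    d = dirs
    ref = np.where(np.abs(d[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (len(d), 1)),
                   np.tile([1.0, 0.0, 0.0], (len(d), 1)))
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    new = d + tx[:, None] * e1 + ty[:, None] * e2
    return new / np.linalg.norm(new, axis=1, keepdims=True)


def _apply_nuclear(interact, e_new, flat, ivox, pos, edep, ledger,
                   local_frac, forward_frac, tail_mfp, rho_nom,
                   mat_idx_grid, scale_grid, h, shape, sum_ea, sum_eb,
                   lq_table, e_u):
    """Remove interacting primaries: deposit the local fraction of the
    residual energy on the spot, spread the forward fraction exponentially
    down the same voxel column (fragment-tail surrogate), and book the
    remainder as escaped."""
    idx = np.where(interact)[0]
    e_res = e_new[idx]
    local = local_frac * e_res
    np.add.at(edep.reshape(-1), flat[idx], local)
    ledger.deposited += float(local.sum())
    if lq_table is not None:
        np.add.at(sum_ea.reshape(-1), flat[idx],
                  local * lq_table.alpha_at(e_u[idx]))
        np.add.at(sum_eb.reshape(-1), flat[idx],
                  local * lq_table.beta_at(e_u[idx]))
    ledger.escaped += float(((1.0 - local_frac - forward_frac)
                             * e_res).sum())
    if forward_frac <= 0.0:
        return
    nz = shape[2]
    z_edges = np.arange(nz + 1) * h[2]
    for k, part in enumerate(idx):
        e_fwd = forward_frac * e_res[k]
        i, j, kz = ivox[part]
        z_here = pos[part, 2]
        # exponential deposition along +z with decay length tail_mfp
        upper = np.maximum(z_edges[kz:nz + 1] - z_here, 0.0)
        cdf = 1.0 - np.exp(-upper / tail_mfp)
        weights = np.diff(cdf)
        dep = e_fwd * weights
        edep[i, j, kz:nz] += dep
        ledger.deposited += float(dep.sum())
        ledger.tail_escaped += float(e_fwd * (1.0 - cdf[-1]))
        if lq_table is not None:
            a_val = lq_table.alpha_at(np.array([e_u[part]]))[0]
            b_val = lq_table.beta_at(np.array([e_u[part]]))[0]
            sum_ea[i, j, kz:nz] += dep * a_val
            sum_eb[i, j, kz:nz] += dep * b_val


# -- derived curves ---------------------------------------------------------

def depth_dose(grid: DoseGrid) -> DepthDoseCurve:
    """Laterally integrated depth dose with batch-variance uncertainty."""
    phantom = grid.phantom
    h_z = phantom.spacing[2]
    nz = phantom.shape[2]
    depths = (np.arange(nz) + 0.5) * h_z
    rho = phantom.density_grid()
    slice_mass_per_area = rho.mean(axis=(0, 1)) * h_z / 10.0  # g/cm^2
    dose = grid.edep.sum(axis=(0, 1)) / grid.n_primaries \
        / slice_mass_per_area
    n_b = grid.batch_depth_dose.shape[0]
    sigma = grid.batch_depth_dose.std(axis=0, ddof=1) / math.sqrt(n_b) \
        if n_b > 1 else np.zeros(nz)
    return DepthDoseCurve(depths, dose, sigma)


def lateral_profile(grid: DoseGrid, depth_mm: float,
                    axis: Literal["x", "y"] = "x"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Transverse dose profile (positions mm, dose MeV/g per primary
    integrated over the other transverse axis) at the slice containing
    ``depth_mm``."""
    phantom = grid.phantom
    nz = phantom.shape[2]
    k = int(depth_mm / phantom.spacing[2])
    if not 0 <= k < nz:
        raise ValueError(f"depth {depth_mm} mm outside phantom")
    slab = grid.dose[:, :, k]
    if axis == "x":
        prof = slab.sum(axis=1) * phantom.spacing[1]
        xs = (np.arange(phantom.shape[0]) + 0.5) * phantom.spacing[0]
    else:
        prof = slab.sum(axis=0) * phantom.spacing[0]
        xs = (np.arange(phantom.shape[1]) + 0.5) * phantom.spacing[1]
    return xs, prof
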