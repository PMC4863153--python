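"""Mixed-field linear-quadratic biological dose.

For a mixed radiation field the per-voxel LQ coefficients are the
dose-weighted averages over all contributing particles

    alpha_bar_j = sum_i d_ij alpha_ij / sum_i d_ij
    beta_bar_j  = sum_i d_ij beta_ij  / sum_i d_ij

and the RBE-weighted dose is the photon dose producing the same LQ effect
E = alpha_bar D + beta_bar D^2:

    D_RBE = sqrt( (alpha_ph / 2 beta_ph)^2 + E / beta_ph )
            - alpha_ph / (2 beta_ph).

The package's reference photon response is (alpha/beta)_ph = 2 Gy with
alpha_ph = 0.1 Gy^-1 and beta_ph = 0.05 Gy^-2; proton plans may instead
use the clinical constant RBE of 1.1.

SOBP weight optimization flattens the RBE-weighted dose over a target
depth interval by iterative multiplicative updates in effect space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhotonReference:
    """Photon LQ response used as the iso-effect reference."""

    alpha_ph: float = 0.1   # Gy^-1
    beta_ph: float = 0.05   # Gy^-2

    def __post_init__(self) -> None:
        if self.alpha_ph <= 0 or self.beta_ph <= 0:
            raise ValueError("photon alpha and beta must be > 0")

    @property
    def alpha_over_beta(self) -> float:
        return self.alpha_ph / self.beta_ph


DEFAULT_PHOTON_REFERENCE = PhotonReference()


@dataclass
class LQCoefficientTable:
    """alpha(E), beta(E) for one species of the mixed field.

    Interpolation is log-linear in energy per nucleon; outside the grid
    the edge values are held (with a warning on first clamp).
    """

    species: str
    energy_grid: np.ndarray  # MeV/u, strictly increasing
    alpha: np.ndarray        # Gy^-1
    beta: np.ndarray         # Gy^-2
    _warned: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("alpha and beta must be >= 0")
        if not (len(self.energy_grid) == len(self.alpha)
                == len(self.beta)):
            raise ValueError("grid/alpha/beta lengths differ")

    def _interp(self, E: np.ndarray, values: np.ndarray) -> np.ndarray:
        e = np.atleast_1d(np.asarray(E, dtype=float))
        lo, hi = self.energy_grid[0], self.energy_grid[-1]
        if (np.any(e < lo) or np.any(e > hi)) and not self._warned:
            log.warning("LQ table %r: energies outside [%g, %g] MeV/u "
                        "clamped to edges", self.species, lo, hi)
            self._warned = True
        e = np.clip(e, lo, hi)
        return np.interp(np.log(e), np.log(self.energy_grid), values)

    def alpha_at(self, E) -> np.ndarray:
        return self._interp(E, self.alpha)

    def beta_at(self, E) -> np.ndarray:
        return self._interp(E, self.beta)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "species": self.species, "E_MeV_u": self.energy_grid,
            "alpha_Gy^-1": self.alpha, "beta_Gy^-2": self.beta,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str | None = None
                 ) -> "LQCoefficientTable":
        df = pd.read_csv(path, comment="#")
        if species is not None:
            df = df[df["species"] == species]
            if df.empty:
                raise KeyError(f"species {species!r} not in {path}")
        else:
            species = str(df["species"].iloc[0])
        return cls(species, df["E_MeV_u"].to_numpy(),
                   df["alpha_Gy^-1"].to_numpy(),
                   df["beta_Gy^-2"].to_numpy())


class MixedFieldAccumulator:
    """Per-voxel running sums sum(d), sum(d alpha), sum(d beta).

    Sums are plain commutative additions of finite non-negative terms, so
    accumulation order cannot change results beyond float addition order;
    deposits are added one at a time (pairwise summation is not needed at
    the accuracy the averages are used)."""

    def __init__(self, shape: tuple[int, ...]):
        self.sum_d = np.zeros(shape)
        self.sum_da = np.zeros(shape)
        self.sum_db = np.zeros(shape)
        self.tables: dict[str, LQCoefficientTable] = {}

    def register(self, table: LQCoefficientTable) -> None:
        self.tables[table.species] = table

    def accumulate(self, voxel, dose: float, species: str,
                   E: float) -> None:
        """Add one deposit of ``dose`` Gy from ``species`` at energy ``E``
        MeV/u into ``voxel`` (an index tuple)."""
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if species not in self.tables:
            raise KeyError(
                f"no LQ table registered for species {species!r}"
            )
        t = self.tables[species]
        self.sum_d[voxel] += dose
        self.sum_da[voxel] += dose * float(t.alpha_at(E)[0])
        self.sum_db[voxel] += dose * float(t.beta_at(E)[0])

    def alpha_bar(self, voxel=None) -> np.ndarray | float:
        return _safe_ratio(self.sum_da, self.sum_d, voxel)

    def beta_bar(self, voxel=None) -> np.ndarray | float:
        return _safe_ratio(self.sum_db, self.sum_d, voxel)


def _safe_ratio(num, den, voxel):
    if voxel is not None:
        d = den[voxel]
        return num[voxel] / d if d > 0 else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return out


def alpha_bar(acc: MixedFieldAccumulator, voxel=None):
    return acc.alpha_bar(voxel)


def beta_bar(acc: MixedFieldAccumulator, voxel=None):
    return acc.beta_bar(voxel)


def rbe_weighted_dose(
    D, alpha_bar, beta_bar,
    ref: PhotonReference = DEFAULT_PHOTON_REFERENCE,
):
    """RBE-weighted dose (Gy (RBE)) by inverting the photon LQ response at
    equal effect.  Array-friendly; D must be >= 0."""
    d = np.asarray(D, dtype=float)
    if np.any(d < 0):
        raise ValueError("absorbed dose must be >= 0")
    effect = np.asarray(alpha_bar) * d + np.asarray(beta_bar) * d**2
    if np.any(effect < 0):
        raise ValueError("negative biological effect is non-physical")
    half = ref.alpha_ph / (2.0 * ref.beta_ph)
    out = np.sqrt(half**2 + effect / ref.beta_ph) - half
    return out if out.ndim else float(out)


def rbe(D, alpha_bar_v, beta_bar_v,
        ref: PhotonReference = DEFAULT_PHOTON_REFERENCE):
    """RBE = D_RBE / D; the low-dose limit alpha_bar/alpha_ph at D = 0."""
    d = np.asarray(D, dtype=float)
    drbe = rbe_weighted_dose(d, alpha_bar_v, beta_bar_v, ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(d > 0, drbe / np.maximum(d, 1e-300),
                     np.asarray(alpha_bar_v) / ref.alpha_ph)
    return r if r.ndim else float(r)


PROTON_CLINICAL_RBE = 1.1


def proton_clinical_rbe(dose_grid: np.ndarray) -> np.ndarray:
    """Constant clinical proton RBE: every voxel multiplied by 1.1."""
    return np.asarray(dose_grid, dtype=float) * PROTON_CLINICAL_RBE


# -- SOBP optimization ------------------------------------------------------

@dataclass
class SOBPComponent:
    """One mono-energetic pencil-beam component of an SOBP.

    Arrays are per unit weight on a shared depth grid: absorbed dose
    ``d`` (Gy), and the dose-weighted LQ sums ``d_alpha = d * alpha`` and
    ``d_beta = d * beta`` of its mixed field.
    """

    energy: float           # MeV/u
    depth_mm: np.ndarray
    d: np.ndarray           # Gy per unit weight
    d_alpha: np.ndarray     # Gy * Gy^-1 per unit weight
    d_beta: np.ndarray      # Gy * Gy^-2 per unit weight


def sobp_component_from_grid(grid) -> SOBPComponent:
    """Build an SOBP component from a simulated dose grid scored with an
    LQ table (``run_simulation(..., lq_table=...)``).

    The component's depth profile is the slice-average dose in Gy per
    primary; weights returned by the optimizer are therefore numbers of
    primaries (times any global fluence scale).
    """
    from .constants import MEV_PER_GRAM_TO_GY
    phantom = grid.phantom
    if grid.sum_edep_alpha is None:
        raise ValueError("grid was not scored with an LQ table")
    vol = float(np.prod([s / 10.0 for s in phantom.spacing]))
    slice_mass = phantom.density_grid().sum(axis=(0, 1)) * vol  # g
    conv = MEV_PER_GRAM_TO_GY / grid.n_primaries
    d = grid.edep.sum(axis=(0, 1)) / slice_mass * conv
    da = grid.sum_edep_alpha.sum(axis=(0, 1)) / slice_mass * conv
    db = grid.sum_edep_beta.sum(axis=(0, 1)) / slice_mass * conv
    nz = phantom.shape[2]
    depth = (np.arange(nz) + 0.5) * phantom.spacing[2]
    return SOBPComponent(grid.beam.nominal_energy, depth, d, da, db)


@dataclass
class SOBPResult:
    weights: np.ndarray
    depth_mm: np.ndarray
    dose: np.ndarray
    d_rbe: np.ndarray
    alpha_bar: np.ndarray
    beta_bar: np.ndarray
    target_mask: np.ndarray
    prescription: float
    mean_deviation: float
    max_deviation: float


def _field_quantities(components, weights):
    d = sum(w * c.d for w, c in zip(weights, components))
    da = sum(w * c.d_alpha for w, c in zip(weights, components))
    db = sum(w * c.d_beta for w, c in zip(weights, components))
    abar = _safe_ratio(da, d, None)
    bbar = _safe_ratio(db, d, None)
    return d, da, db, abar, bbar


def optimize_sobp(
    components: Sequence[SOBPComponent],
    target: tuple[float, float],
    prescription: float,
    ref: PhotonReference = DEFAULT_PHOTON_REFERENCE,
    mode: str = "lq",
    max_iter: int = 20000,
    tol: float = 1e-12,
) -> SOBPResult:
    """Non-negative component weights flattening the prescription over the
    target depth interval.

    ``mode="lq"`` matches the photon-equivalent effect of the prescription
    (D_RBE == prescription); ``mode="physical"`` flattens the absorbed
    dose itself.  Both use deterministic iterative multiplicative updates
    (NMF-style), which preserve non-negativity without projection.
    """
    if not components:
        raise ValueError("need at least one SOBP component")
    depth = components[0].depth_mm
    for c in components:
        if not np.array_equal(c.depth_mm, depth):
            raise ValueError("components must share a depth grid")
    z_lo, z_hi = target
    mask = (depth >= z_lo) & (depth <= z_hi)
    if not mask.any():
        raise ValueError("target interval contains no depth grid points")
    peaks = [c.depth_mm[np.argmax(c.d)] for c in components]
    # allow a two-bin grace for half-bin grid offsets of the peak sample
    if max(peaks) < z_hi - 2.0 * (depth[1] - depth[0]):
        raise ValueError(
            f"infeasible prescription: deepest component peak at "
            f"{max(peaks):.1f} mm is short of the target distal edge "
            f"{z_hi:.1f} mm"
        )

    n_c = len(components)
    d_mat = np.stack([c.d[mask] for c in components])        # (n_c, n_z)
    a_mat = np.stack([c.d_alpha[mask] for c in components])
    b_mat = np.stack([c.d_beta[mask] for c in components])

    if mode == "physical":
        target_vec = np.full(mask.sum(), prescription)
        w = np.full(n_c, prescription / max(d_mat.sum(axis=0).mean(),
                                            1e-30))
        for _ in range(max_iter):
            model = w @ d_mat
            num = d_mat @ target_vec
            den = d_mat @ model
            w_new = w * num / np.maximum(den, 1e-300)
            if np.max(np.abs(w_new - w)) <= tol * np.max(w_new):
                w = w_new
                break
            w = w_new
    elif mode == "lq":
        effect_target = ref.alpha_ph * prescription \
            + ref.beta_ph * prescription**2
        target_vec = np.full(mask.sum(), effect_target)
        w = np.full(n_c, prescription / max(d_mat.sum(axis=0).mean(),
                                            1e-30))
        for _ in range(max_iter):
            dose = w @ d_mat
            a_sum = w @ a_mat
            b_sum = w @ b_mat
            effect = a_sum + b_sum * dose
            # d(effect)/dw_k = a_k + b_k * dose + b_sum * d_k
            grad_k = a_mat + b_mat * dose + d_mat * (w @ b_mat)
            num = grad_k @ target_vec
            den = grad_k @ effect
            w_new = w * num / np.maximum(den, 1e-300)
            if np.max(np.abs(w_new - w)) <= tol * np.max(w_new):
                w = w_new
                break
            w = w_new
    else:
        raise ValueError(f"unknown mode {mode!r}")

    d, da, db, abar, bbar = _field_quantities(components, w)
    d_rbe = rbe_weighted_dose(d, abar, bbar, ref) if mode == "lq" else d
    dev = d_rbe[mask] - prescription
    return SOBPResult(
        weights=w, depth_mm=depth, dose=d, d_rbe=d_rbe, alpha_bar=abar,
        beta_bar=bbar, target_mask=mask, prescription=prescription,
        mean_deviation=float(np.mean(dev)),
        max_deviation=float(np.max(np.abs(dev))),
    )
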