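"""Electronic stopping power for therapeutic ions.

Implements the corrected Bethe-Bloch mass stopping power

    S/rho = (2 pi n_e r_e^2 m_e c^2 / rho) * z_eff^2 / beta^2 *
            [ ln( 2 m_e c^2 beta^2 T_max / (I^2 (1 - beta^2)) )
              - 2 beta^2 + 2 z L1 + 2 z^2 L2 + K_M - 2 C/Z - delta ]

with the maximum kinematically allowed energy transfer to a free electron

    T_max = 2 m_e c^2 beta^2 gamma^2 / (1 + 2 gamma m_e/M + (m_e/M)^2)

kept in full (no heavy-projectile truncation of the m_e/M terms).  The
higher-order terms are: the Sternheimer density effect ``delta``, the
Barkas-Berger shell correction ``C/Z``, the z^3 Barkas and z^4 Bloch
corrections ``L1``/``L2``, and a Mott-cross-section correction ``K_M``.
The Bloch term uses the exact standard series; the Barkas and Mott terms
are smooth surrogate parameterizations (flagged in
:func:`surrogate_models`), adequate for the sub-percent role they play at
therapeutic energies.

Restricted stopping (delta-ray production threshold), CSDA ranges and
log-grid tables for transport are provided alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, special
from scipy.interpolate import PchipInterpolator

from .constants import CONSTANTS
from .materials import Material

log = logging.getLogger(__name__)

#: Operating domain accepted by the stopping functions, MeV/u.
E_MIN, E_MAX = 0.01, 1000.0

#: Below this energy the Bethe bracket is unreliable and a Ziegler-style
#: velocity-proportional stopping S ~ sqrt(E), matched at this point, is
#: substituted (residual range below it is micrometre-scale).
E_BETHE_MIN = 0.5


@dataclass(frozen=True)
class ProjectileSpec:
    """A heavy charged projectile (fully specified by charge, mass, A)."""

    name: str
    charge_number: int  # z
    mass: float         # rest mass, MeV/c^2 (nuclear mass)
    mass_number: int    # A

    def __post_init__(self) -> None:
        if self.charge_number < 1:
            raise ValueError("charge_number must be >= 1")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.mass_number < 1:
            raise ValueError("mass_number must be >= 1")


PROTON = ProjectileSpec("proton", 1, 938.27208816, 1)
HELIUM = ProjectileSpec("helium", 2, 3727.379378, 4)
CARBON = ProjectileSpec("carbon", 6, 11174.862, 12)
OXYGEN = ProjectileSpec("oxygen", 8, 14895.079, 16)

PROJECTILES = {p.name: p for p in (PROTON, HELIUM, CARBON, OXYGEN)}


@dataclass(frozen=True)
class KinematicState:
    kinetic_energy_per_nucleon: float  # MeV/u
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        # recovering gamma from beta is ill-conditioned (error ~ gamma^2
        # ulp(beta)), so the consistency band widens with gamma^3
        if abs(self.gamma - 1.0 / math.sqrt(1.0 - self.beta**2)) \
                > 1e-12 * self.gamma**3:
            raise ValueError("gamma inconsistent with beta")


def kinematics_from_energy(E: float, projectile: ProjectileSpec
                           ) -> KinematicState:
    """Relativistic beta, gamma from kinetic energy per nucleon (MeV/u)."""
    if E <= 0:
        raise ValueError("kinetic energy must be > 0")
    gamma = 1.0 + E * projectile.mass_number / projectile.mass
    beta = math.sqrt(1.0 - 1.0 / gamma**2)
    return KinematicState(E, beta, gamma)


def energy_from_kinematics(state: KinematicState,
                           projectile: ProjectileSpec) -> float:
    return (state.gamma - 1.0) * projectile.mass / projectile.mass_number


def tmax(state: KinematicState, projectile: ProjectileSpec) -> float:
    """Maximum energy transfer to a stationary electron (MeV), all mass
    ratio terms kept."""
    me = CONSTANTS.electron_mass_energy
    ratio = me / projectile.mass
    b2g2 = state.beta**2 * state.gamma**2
    return 2.0 * me * b2g2 / (1.0 + 2.0 * state.gamma * ratio + ratio**2)


@dataclass(frozen=True)
class StoppingOptions:
    """Toggles and constants for the correction terms of the stopping
    formula.  ``mott`` may be True, False or ``"auto"`` (on for z >= 3)."""

    density: bool = True
    shell: bool = True
    barkas: bool = True
    bloch: bool = True
    mott: bool | str = "auto"
    effective_charge_k: float = 125.0
    mott_scale: float = 1.0

    def mott_enabled(self, projectile: ProjectileSpec) -> bool:
        if self.mott == "auto":
            return projectile.charge_number >= 3
        return bool(self.mott)


DEFAULT_OPTIONS = StoppingOptions()

ALL_OFF = StoppingOptions(density=False, shell=False, barkas=False,
                          bloch=False, mott=False)


def surrogate_models() -> dict[str, str]:
    """Names and one-line descriptions of the surrogate parameterizations
    in use, for run-header metadata."""
    return {
        "barkas_L1": "Jackson-McCarthy-style scaled-velocity fit "
                     "(bespoke re-fit unavailable)",
        "mott_KM": "Born-parameter rational surrogate for the Mott "
                   "stopping correction",
        "shell_C": "Barkas-Berger eta-power fit extracted from proton "
                   "stopping tabulations",
        "low_energy": "Ziegler-style velocity-proportional stopping below "
                      f"{E_MIN} MeV/u",
    }


def effective_charge(projectile: ProjectileSpec, state: KinematicState,
                     options: StoppingOptions = DEFAULT_OPTIONS) -> float:
    """Barkas-type effective charge; exact z for protons and alphas."""
    z = projectile.charge_number
    if z <= 2:
        return float(z)
    k = options.effective_charge_k
    return z * (1.0 - math.exp(-k * state.beta * z ** (-2.0 / 3.0)))


# -- Sternheimer density effect --------------------------------------------

#: Published Sternheimer coefficients (x0, x1, Cbar, a, m, delta0) for
#: materials where the generic prescription is not used.
STERNHEIMER_PARAMS: dict[str, tuple[float, float, float, float, float, float]] = {
    "water": (0.2400, 2.8004, 3.5017, 0.09116, 3.4773, 0.0),
}


def _sternheimer_generic(material: Material
                         ) -> tuple[float, float, float, float, float, float]:
    """Generic Sternheimer-Peierls parameters from I and the plasma
    energy (non-conductor rules)."""
    i_ev = material.mean_excitation_energy
    plasma_ev = 28.8159 * math.sqrt(material.density * material.z_over_a)
    cbar = 2.0 * math.log(i_ev / plasma_ev) + 1.0
    if i_ev < 100.0:
        x1 = 2.0
        x0 = 0.2 if cbar < 3.681 else 0.326 * cbar - 1.0
    else:
        x1 = 3.0
        x0 = 0.2 if cbar < 5.215 else 0.326 * cbar - 1.5
    m = 3.0
    a = (cbar - 2.0 * math.log(10.0) * x0) / (x1 - x0) ** m
    return (x0, x1, cbar, a, m, 0.0)


def density_correction(state: KinematicState, material: Material) -> float:
    """Sternheimer density-effect delta(beta*gamma) >= 0."""
    params = STERNHEIMER_PARAMS.get(material.name)
    if params is None:
        params = _sternheimer_generic(material)
    x0, x1, cbar, a, m, delta0 = params
    x = math.log10(state.beta * state.gamma)
    two_ln10 = 2.0 * math.log(10.0)
    if x < x0:
        return delta0 * 10.0 ** (2.0 * (x - x0)) if delta0 else 0.0
    if x < x1:
        return two_ln10 * x - cbar + a * (x1 - x) ** m
    return two_ln10 * x - cbar


# -- shell correction -------------------------------------------------------

#: Validity floor of the Barkas-Berger fit in eta = beta*gamma.
_SHELL_ETA_MIN = 0.13
_shell_clamp_warned = False


def shell_correction(state: KinematicState, material: Material) -> float:
    """Shell correction C/Z from the Barkas-Berger eta-power fit.

    The fit was extracted from proton stopping tabulations; below its
    validity domain eta is clamped (warned once per process) so the term
    stays bounded and continuous.
    """
    global _shell_clamp_warned
    eta = state.beta * state.gamma
    if eta < _SHELL_ETA_MIN:
        if not _shell_clamp_warned:
            log.warning(
                "shell correction clamped below eta=%.3g (first at "
                "E=%.3g MeV/u); further clamps logged at DEBUG",
                _SHELL_ETA_MIN, state.kinetic_energy_per_nucleon)
            _shell_clamp_warned = True
        else:
            log.debug("shell correction clamped at eta=%.3g", eta)
        eta = _SHELL_ETA_MIN
    i_ev = material.mean_excitation_energy
    e2, e4, e6 = eta**-2, eta**-4, eta**-6
    c = ((0.422377 * e2 + 0.0304043 * e4 - 0.00038106 * e6) * 1e-6 * i_ev**2
         + (3.850190 * e2 - 0.1667989 * e4 + 0.00157955 * e6)
         * 1e-9 * i_ev**3)
    return c / material.mean_z


# -- Barkas and Bloch terms -------------------------------------------------

def barkas_bloch_terms(projectile: ProjectileSpec, state: KinematicState,
                       material: Material,
                       options: StoppingOptions = DEFAULT_OPTIONS
                       ) -> tuple[float, float]:
    """(L1, L2) entering the bracket as ``2 z L1 + 2 z^2 L2``.

    L2 is the exact Bloch series  z^2 L2 = psi(1) - Re psi(1 + i y),
    y = z_eff alpha / beta.  L1 is a smooth Jackson-McCarthy-style
    surrogate in the scaled velocity V = beta gamma / (alpha sqrt(Z)).
    """
    alpha = CONSTANTS.fine_structure_constant
    zt = material.mean_z
    v = state.beta * state.gamma / (alpha * math.sqrt(zt))
    # surrogate F(V): rises ~V^2 at small V, saturates; L1 ~ V^-3 at high V
    f_v = 0.5 * v**2 / (1.0 + v**2)
    l1 = f_v / (math.sqrt(zt) * v**3)

    zeff = effective_charge(projectile, state, options)
    y = zeff * alpha / state.beta
    bloch = float(special.digamma(1.0).real
                  - special.digamma(1.0 + 1j * y).real)
    l2 = bloch / projectile.charge_number**2
    return l1, l2


def mott_correction(projectile: ProjectileSpec, state: KinematicState,
                    options: StoppingOptions = DEFAULT_OPTIONS) -> float:
    """Mott-cross-section stopping correction K_M (surrogate).

    Vanishes in the Born limit z*alpha/beta << 1 and grows with projectile
    charge; returns 0 when the toggle is off.
    """
    if not options.mott_enabled(projectile):
        return 0.0
    zeff = effective_charge(projectile, state, options)
    chi = zeff * CONSTANTS.fine_structure_constant / state.beta
    return options.mott_scale * chi**2 / (1.0 + chi**2)


# -- the assembled formula --------------------------------------------------

def _bracket(E: float, projectile: ProjectileSpec, material: Material,
             options: StoppingOptions) -> tuple[float, float, float]:
    state = kinematics_from_energy(E, projectile)
    beta2 = state.beta**2
    i_mev = material.mean_excitation_energy * 1e-6
    t_max = tmax(state, projectile)
    me = CONSTANTS.electron_mass_energy
    log_arg = 2.0 * me * beta2 * t_max / (i_mev**2 * (1.0 - beta2))
    bracket = math.log(log_arg) - 2.0 * beta2
    z = projectile.charge_number
    if options.barkas or options.bloch:
        l1, l2 = barkas_bloch_terms(projectile, state, material, options)
        if options.barkas:
            bracket += 2.0 * z * l1
        if options.bloch:
            bracket += 2.0 * z**2 * l2
    bracket += mott_correction(projectile, state, options)
    if options.shell:
        bracket -= 2.0 * shell_correction(state, material)
    if options.density:
        bracket -= density_correction(state, material)
    zeff = effective_charge(projectile, state, options)
    return bracket, beta2, zeff


def electronic_stopping_power(
    E: float,
    projectile: ProjectileSpec,
    material: Material,
    options: StoppingOptions = DEFAULT_OPTIONS,
) -> float:
    """Unrestricted mass electronic stopping power in MeV cm^2/g.

    Below the operating floor a Ziegler-style velocity-proportional
    stopping ``S(E) = S(E_min) sqrt(E/E_min)`` is substituted.
    """
    if E <= 0:
        raise ValueError("energy must be > 0")
    if E < E_BETHE_MIN:
        return electronic_stopping_power(E_BETHE_MIN, projectile, material,
                                         options) * math.sqrt(E / E_BETHE_MIN)
    if E > E_MAX:
        raise ValueError(f"E={E} MeV/u above operating domain {E_MAX}")
    bracket, beta2, zeff = _bracket(E, projectile, material, options)
    if bracket <= 0:
        raise ValueError(
            f"non-positive stopping bracket ({bracket:.3g}) for "
            f"{projectile.name} at {E} MeV/u in {material.name}"
        )
    pref = (2.0 * math.pi * material.electron_density
            * CONSTANTS.classical_electron_radius**2
            * CONSTANTS.electron_mass_energy * zeff**2 / beta2)
    return pref * bracket / material.density


def restricted_stopping_power(
    E: float,
    projectile: ProjectileSpec,
    material: Material,
    delta_threshold: float,
    options: StoppingOptions = DEFAULT_OPTIONS,
) -> float:
    """Restricted mass stopping power with energy transfers capped at the
    delta-ray production threshold (MeV).

    Uses the standard restricted form: T_max -> T_up = min(T_max, cut) in
    the logarithm and ``- beta^2 (1 + T_up/T_max)`` in place of
    ``- 2 beta^2``; equals the unrestricted value when the threshold is at
    or above T_max.
    """
    if delta_threshold < 1e-3:
        raise ValueError("delta-ray threshold below 1 keV is not supported")
    if E < E_BETHE_MIN:
        return restricted_stopping_power(E_BETHE_MIN, projectile, material,
                                         delta_threshold, options) \
            * math.sqrt(E / E_BETHE_MIN)
    state = kinematics_from_energy(E, projectile)
    t_max = tmax(state, projectile)
    if delta_threshold >= t_max:
        return electronic_stopping_power(E, projectile, material, options)
    t_up = delta_threshold
    bracket, beta2, zeff = _bracket(E, projectile, material, options)
    # swap the unrestricted log/beta^2 terms for the restricted ones
    bracket += math.log(t_up / t_max) + 2.0 * beta2 \
        - beta2 * (1.0 + t_up / t_max)
    if bracket <= 0:
        raise ValueError("non-positive restricted stopping bracket")
    pref = (2.0 * math.pi * material.electron_density
            * CONSTANTS.classical_electron_radius**2
            * CONSTANTS.electron_mass_energy * zeff**2 / beta2)
    return pref * bracket / material.density


def delta_ray_spectrum_mean_energy(
    E: float, projectile: ProjectileSpec, material: Material,
    delta_threshold: float,
) -> float:
    """Mean energy flux (MeV cm^2/g) into delta rays above the threshold,
    from the free-electron (Rutherford) transfer spectrum; by construction
    restricted + this = unrestricted up to the spectrum approximation."""
    unres = electronic_stopping_power(E, projectile, material)
    res = restricted_stopping_power(E, projectile, material, delta_threshold)
    return unres - res


def csda_range(
    E: float,
    projectile: ProjectileSpec,
    material: Material,
    options: StoppingOptions = DEFAULT_OPTIONS,
    rtol: float = 1e-6,
) -> float:
    """CSDA range in g/cm^2: integral of A dE'/S(E') from 0 to E (E in
    MeV/u), adaptive quadrature plus the analytic velocity-proportional
    tail below the operating floor."""
    if E <= 0:
        return 0.0
    a = projectile.mass_number
    e_m = E_BETHE_MIN
    s_m = electronic_stopping_power(e_m, projectile, material, options)
    if E <= e_m:
        # S ~ S(e_m) sqrt(E'/e_m) integrates to 2 A sqrt(e_m E) / S(e_m)
        return 2.0 * a * math.sqrt(e_m * E) / s_m
    tail = 2.0 * a * e_m / s_m
    val, err = integrate.quad(
        lambda e: a / electronic_stopping_power(e, projectile, material,
                                                options),
        e_m, E, epsrel=rtol, limit=200,
    )
    if not math.isfinite(val):
        raise RuntimeError(
            f"CSDA quadrature failed on [{E_MIN}, {E}] MeV/u")
    return tail + val


def energy_at_range(
    R: float, projectile: ProjectileSpec, material: Material,
    options: StoppingOptions = DEFAULT_OPTIONS,
) -> float:
    """Inverse of :func:`csda_range` by bisection (E in MeV/u)."""
    if R <= 0:
        raise ValueError("range must be > 0")
    lo, hi = E_MIN, E_MAX
    if csda_range(hi, projectile, material, options) < R:
        raise ValueError("range beyond operating domain")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if csda_range(mid, projectile, material, options) < R:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


# -- tables for transport ---------------------------------------------------

@dataclass
class StoppingTable:
    """Log-spaced stopping/range table with monotone interpolation.

    Built once per (projectile, material) pair; evaluation during
    transport is a vectorized log-log interpolation.
    """

    projectile: ProjectileSpec
    material: Material
    energies: np.ndarray      # MeV/u
    stopping: np.ndarray      # MeV cm^2/g
    ranges: np.ndarray        # g/cm^2
    _log_e: np.ndarray = field(init=False)
    _log_s: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self._log_e = np.log(self.energies)
        self._log_s = np.log(self.stopping)
        self._range_interp = PchipInterpolator(self._log_e,
                                               np.log(self.ranges))

    @classmethod
    def build(
        cls,
        projectile: ProjectileSpec,
        material: Material,
        e_min: float = E_MIN,
        e_max: float = E_MAX,
        points_per_decade: int = 200,
        options: StoppingOptions = DEFAULT_OPTIONS,
    ) -> "StoppingTable":
        n = max(8, int(points_per_decade * math.log10(e_max / e_min)))
        energies = np.geomspace(e_min, e_max, n)
        stopping = np.array([
            electronic_stopping_power(e, projectile, material, options)
            for e in energies
        ])
        # cumulative range by trapezoid on the fine grid (cheap, accurate)
        inv = projectile.mass_number / stopping
        tail = 2.0 * projectile.mass_number * energies[0] / stopping[0]
        ranges = tail + np.concatenate(
            ([0.0], np.cumsum(0.5 * (inv[1:] + inv[:-1])
                              * np.diff(energies)))
        )
        return cls(projectile, material, energies, stopping, ranges)

    def stopping_at(self, E: np.ndarray) -> np.ndarray:
        """Vectorized S(E) in MeV cm^2/g (sqrt extrapolation below grid)."""
        e = np.asarray(E, dtype=float)
        below = e < self.energies[0]
        ec = np.clip(e, self.energies[0], self.energies[-1])
        s = np.exp(np.interp(np.log(ec), self._log_e, self._log_s))
        if np.any(below):
            s = np.where(below,
                         s * np.sqrt(np.maximum(e, 1e-12)
                                     / self.energies[0]), s)
        return s

    def range_at(self, E: np.ndarray) -> np.ndarray:
        e = np.clip(np.asarray(E, dtype=float),
                    self.energies[0], self.energies[-1])
        return np.exp(self._range_interp(np.log(e)))


def export_stopping_csv(
    path, projectile: ProjectileSpec, material: Material,
    delta_threshold: float = 0.1,
    energies: np.ndarray | None = None,
) -> None:
    """Write (E, S_el, S_restricted, range) as CSV for cross-tool checks."""
    import pandas as pd
    if energies is None:
        energies = np.geomspace(0.1, 500.0, 60)
    rows = [
        (e,
         electronic_stopping_power(e, projectile, material),
         restricted_stopping_power(e, projectile, material,
                                   delta_threshold),
         csda_range(e, projectile, material))
        for e in energies
    ]
    pd.DataFrame(rows, columns=["E_MeV_u", "S_el_MeV_cm2_g",
                                "S_restricted_MeV_cm2_g",
                                "range_g_cm2"]).to_csv(path, index=False)
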