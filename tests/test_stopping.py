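"""Stopping power: kinematics, correction terms, assembly, ranges.

The key oracle is an independent literal transcription of the corrected
Bethe-Bloch formula (own constants, own assembly) used to pin the
in-package implementation to 1e-10.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from iondose.materials import BONE, PMMA, WATER, make_material
from iondose import stopping as sp
from iondose.stopping import (
    ALL_OFF, CARBON, DEFAULT_OPTIONS, PROTON, StoppingOptions,
    StoppingTable, csda_range, effective_charge, electronic_stopping_power,
    energy_from_kinematics, kinematics_from_energy,
    restricted_stopping_power, tmax,
)

# independent constants for the oracle transcriptions (PDG values,
# intentionally typed in separately from the package's constants module)
ME_C2 = 0.51099895000
RE_CM = 2.8179403262e-13
MP = 938.27208816


def bethe_oracle(E, z, mass, a_nuc, n_e, i_ev, rho):
    """Literal textbook Bethe formula (no corrections, z_eff = z):
    independent transcription used as the reduction oracle."""
    gamma = 1.0 + E * a_nuc / mass
    beta2 = 1.0 - 1.0 / gamma**2
    me_over_m = ME_C2 / mass
    t_max = (2.0 * ME_C2 * beta2 * gamma**2
             / (1.0 + 2.0 * gamma * me_over_m + me_over_m**2))
    i_mev = i_ev * 1e-6
    bracket = math.log(2.0 * ME_C2 * beta2 * t_max
                       / (i_mev**2 * (1.0 - beta2))) - 2.0 * beta2
    pref = 2.0 * math.pi * n_e * RE_CM**2 * ME_C2 * z**2 / beta2
    return pref * bracket / rho


class TestKinematics:
    def test_proton_at_rest_mass_energy_gives_gamma_2(self):
        state = kinematics_from_energy(938.27208816, PROTON)
        assert state.gamma == pytest.approx(2.0, rel=1e-12)
        assert state.beta == pytest.approx(math.sqrt(3) / 2, rel=1e-12)

    def test_low_energy_limit(self):
        assert kinematics_from_energy(1e-6, PROTON).beta < 1e-3

    @given(st_hyp.floats(min_value=0.1, max_value=900.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_round_trip_inverts(self, e):
        state = kinematics_from_energy(e, CARBON)
        assert energy_from_kinematics(state, CARBON) \
            == pytest.approx(e, rel=1e-10)

    @given(st_hyp.floats(min_value=0.1, max_value=400.0),
           st_hyp.floats(min_value=1.01, max_value=2.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_beta_monotone_in_energy(self, e, factor):
        assert kinematics_from_energy(e * factor, PROTON).beta \
            > kinematics_from_energy(e, PROTON).beta

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            kinematics_from_energy(0.0, PROTON)


class TestTmax:
    def test_vanishes_with_beta(self):
        state = kinematics_from_energy(1e-5, PROTON)
        assert tmax(state, PROTON) < 1e-7

    def test_heavy_projectile_limit(self):
        # for carbon the mass-ratio terms are tiny: Tmax ~ 2 me b^2 g^2
        state = kinematics_from_energy(200.0, CARBON)
        approx = 2 * ME_C2 * state.beta**2 * state.gamma**2
        assert tmax(state, CARBON) == pytest.approx(approx, rel=3e-4)

    def test_200mev_proton_against_hand_evaluation(self):
        state = kinematics_from_energy(200.0, PROTON)
        gamma = 1.0 + 200.0 / MP
        beta2 = 1.0 - 1.0 / gamma**2
        r = ME_C2 / MP
        expected = 2 * ME_C2 * beta2 * gamma**2 \
            / (1 + 2 * gamma * r + r**2)
        assert tmax(state, PROTON) == pytest.approx(expected, rel=1e-12)


class TestEffectiveCharge:
    def test_proton_always_fully_stripped(self):
        for e in (0.1, 1.0, 100.0):
            assert effective_charge(PROTON,
                                    kinematics_from_energy(e, PROTON)) == 1.0

    def test_carbon_limits(self):
        hi = effective_charge(CARBON, kinematics_from_energy(900.0, CARBON))
        lo = effective_charge(CARBON, kinematics_from_energy(0.001, CARBON))
        assert hi == pytest.approx(6.0, abs=1e-6)
        assert lo < 0.5

    def test_monotone_in_beta(self):
        es = np.geomspace(0.01, 500, 40)
        zs = [effective_charge(CARBON, kinematics_from_energy(e, CARBON))
              for e in es]
        assert np.all(np.diff(zs) >= 0)


class TestDensityCorrection:
    def test_zero_below_threshold_in_water(self):
        # beta*gamma = 0.1 is below the water x0 knot
        e = (math.sqrt(1.0 + 0.1**2) - 1.0) * MP
        state = kinematics_from_energy(e, PROTON)
        assert sp.density_correction(state, WATER) == 0.0

    def test_non_decreasing(self):
        es = np.geomspace(1.0, 999.0, 50)
        ds = [sp.density_correction(kinematics_from_energy(e, PROTON),
                                    WATER) for e in es]
        assert np.all(np.diff(ds) >= 0)

    def test_asymptotic_slope(self):
        # at large beta*gamma, delta ~ 2 ln(bg) - Cbar: check the 2 ln
        # slope within 1% between bg = 500 and 1000
        def delta_at(bg):
            e = (math.sqrt(1.0 + bg**2) - 1.0) * MP
            return sp.density_correction(kinematics_from_energy(e, PROTON),
                                         WATER)
        slope = (delta_at(1000.0) - delta_at(500.0)) / math.log(2.0)
        assert slope == pytest.approx(2.0, rel=0.01)

    def test_generic_fallback_for_unlisted_material(self):
        # bone has no packaged Sternheimer row; the generic prescription
        # must yield a positive delta once beta*gamma clears its x0 knot
        state = kinematics_from_energy(900.0, PROTON)
        assert sp.density_correction(state, BONE) > 0.0


class TestShellCorrection:
    def test_small_at_high_energy(self):
        state = kinematics_from_energy(1000.0, PROTON)
        assert abs(sp.shell_correction(state, WATER)) < 1e-3

    def test_continuous_in_energy(self):
        es = np.geomspace(2.0, 900.0, 300)
        cs = np.array([sp.shell_correction(kinematics_from_energy(e, PROTON),
                                           WATER) for e in es])
        assert np.all(np.abs(np.diff(cs)) < 0.05 * (np.abs(cs[:-1]) + 1e-4))

    def test_larger_at_low_energy(self):
        lo = sp.shell_correction(kinematics_from_energy(5.0, PROTON), WATER)
        hi = sp.shell_correction(kinematics_from_energy(500.0, PROTON),
                                 WATER)
        assert abs(lo) > abs(hi)


class TestBarkasBlochMott:
    def test_born_limit_small_against_leading_log(self):
        state = kinematics_from_energy(500.0, PROTON)
        l1, l2 = sp.barkas_bloch_terms(PROTON, state, WATER)
        assert abs(2 * l1 + 2 * l2) < 0.05  # leading log is ~18 here

    def test_bloch_vanishes_at_small_y(self):
        state = kinematics_from_energy(900.0, PROTON)
        _, l2 = sp.barkas_bloch_terms(PROTON, state, WATER)
        y = 1 * 7.297e-3 / state.beta
        assert abs(l2) < 2 * y**2 * 1.21  # ~ y^2 zeta(3)

    def test_barkas_odd_in_charge_sign(self):
        # the term enters as 2 z L1: flipping z flips the contribution
        state = kinematics_from_energy(100.0, PROTON)
        l1, _ = sp.barkas_bloch_terms(PROTON, state, WATER)
        assert (2 * (+1) * l1) == -(2 * (-1) * l1)
        assert l1 > 0.0

    def test_mott_disabled_returns_zero(self):
        state = kinematics_from_energy(100.0, CARBON)
        off = StoppingOptions(mott=False)
        assert sp.mott_correction(CARBON, state, off) == 0.0

    def test_mott_grows_with_charge(self):
        opts = StoppingOptions(mott=True)
        e = 100.0
        km_p = sp.mott_correction(PROTON, kinematics_from_energy(e, PROTON),
                                  opts)
        km_c = sp.mott_correction(CARBON, kinematics_from_energy(e, CARBON),
                                  opts)
        assert abs(km_c) > abs(km_p)

    def test_mott_vanishes_in_born_limit(self):
        opts = StoppingOptions(mott=True)
        state = kinematics_from_energy(950.0, PROTON)
        assert abs(sp.mott_correction(PROTON, state, opts)) < 1e-3


class TestStoppingAssembly:
    def test_reduces_to_textbook_bethe_on_grid(self):
        """All corrections off: match the independent transcription to
        1e-10 on a 100-point (E, material) grid."""
        materials = [WATER, BONE, PMMA, make_material("c", {"C": 1.0}, 2.0)]
        energies = np.geomspace(1.0, 900.0, 25)
        for mat in materials:
            for e in energies:
                ours = electronic_stopping_power(e, PROTON, mat, ALL_OFF)
                oracle = bethe_oracle(e, 1, PROTON.mass, 1,
                                      mat.electron_density,
                                      mat.mean_excitation_energy,
                                      mat.density)
                assert ours == pytest.approx(oracle, rel=1e-10)

    def test_charge_squared_scaling_at_fixed_beta(self):
        # same beta for carbon and proton; z-odd/z^2 corrections off
        opts = StoppingOptions(barkas=False, bloch=False, mott=False,
                               shell=False, density=False)
        e_p = 200.0
        gamma = 1.0 + e_p / PROTON.mass
        e_c = (gamma - 1.0) * CARBON.mass / CARBON.mass_number
        s_p = electronic_stopping_power(e_p, PROTON, WATER, opts)
        s_c = electronic_stopping_power(e_c, CARBON, WATER, opts)
        z_p = effective_charge(PROTON, kinematics_from_energy(e_p, PROTON))
        z_c = effective_charge(CARBON, kinematics_from_energy(e_c, CARBON))
        # Tmax differs slightly through the mass terms; 0.5% is ample
        assert s_c / s_p == pytest.approx((z_c / z_p) ** 2, rel=5e-3)

    def test_linear_in_electron_density(self):
        double = WATER.with_density(2.0)
        s1 = electronic_stopping_power(150.0, PROTON, WATER, ALL_OFF)
        s2 = electronic_stopping_power(150.0, PROTON, double, ALL_OFF)
        # mass stopping: n_e doubles but so does rho -> equal
        assert s2 == pytest.approx(s1, rel=1e-12)

    def test_single_maximum_over_domain(self):
        es = np.geomspace(0.02, 900.0, 400)
        s = np.array([electronic_stopping_power(e, PROTON, WATER)
                      for e in es])
        i_pk = int(np.argmax(s))
        assert np.all(np.diff(s[: i_pk + 1]) >= 0) or i_pk < 3
        assert np.all(np.diff(s[i_pk:]) <= 0)

    def test_positive_over_domain(self):
        for e in np.geomspace(0.02, 999.0, 60):
            assert electronic_stopping_power(e, CARBON, WATER) > 0

    def test_reference_proton_water_grid_within_2_percent(self):
        """Regression guard against the packaged ICRU-49/PSTAR-style
        proton-in-water tabulation."""
        import pandas as pd
        from importlib import resources
        path = resources.files("iondose") / "data" \
            / "proton_water_reference_stopping.csv"
        ref = pd.read_csv(str(path), comment="#")
        for _, row in ref.iterrows():
            ours = electronic_stopping_power(row.E_MeV_u, PROTON, WATER)
            assert ours == pytest.approx(row.S_MeV_cm2_g, rel=0.02)


class TestRestrictedStopping:
    def test_equals_unrestricted_above_tmax(self):
        state = kinematics_from_energy(150.0, PROTON)
        t = tmax(state, PROTON)
        assert restricted_stopping_power(150.0, PROTON, WATER, 2 * t) \
            == electronic_stopping_power(150.0, PROTON, WATER)

    @given(st_hyp.floats(min_value=1e-3, max_value=0.3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_never_exceeds_unrestricted(self, cut):
        r = restricted_stopping_power(150.0, PROTON, WATER, cut)
        assert r <= electronic_stopping_power(150.0, PROTON, WATER) + 1e-12

    def test_threshold_below_1kev_rejected(self):
        with pytest.raises(ValueError, match="1 keV"):
            restricted_stopping_power(150.0, PROTON, WATER, 5e-4)

    def test_delta_energy_flux_closes_the_difference(self):
        """Unrestricted = restricted + the energy flux into deltas above
        the cut, computed from the free-electron transfer spectrum."""
        from iondose.constants import CONSTANTS
        e, cut = 150.0, 0.01
        state = kinematics_from_energy(e, PROTON)
        t_max = tmax(state, PROTON)
        beta2 = state.beta**2
        # Rutherford spectrum energy moment (spin-0 form):
        # dS = K [ln(Tmax/Tcut) - beta^2 (1 - Tcut/Tmax)]
        k_pref = (2 * math.pi * WATER.electron_density
                  * CONSTANTS.classical_electron_radius**2
                  * CONSTANTS.electron_mass_energy / beta2) / WATER.density
        flux = k_pref * (math.log(t_max / cut)
                         - beta2 * (1.0 - cut / t_max))
        diff = electronic_stopping_power(e, PROTON, WATER) \
            - restricted_stopping_power(e, PROTON, WATER, cut)
        assert diff == pytest.approx(flux, rel=1e-6)


class TestCSDARange:
    def test_zero_at_zero_energy(self):
        assert csda_range(0.0, PROTON, WATER) == 0.0

    def test_strictly_increasing(self):
        es = np.geomspace(1.0, 500.0, 20)
        rs = [csda_range(e, PROTON, WATER) for e in es]
        assert np.all(np.diff(rs) > 0)

    def test_adaptive_vs_brute_force_trapezoid(self):
        """Adaptive quadrature against a 10^5-point trapezoid oracle."""
        e_hi = 150.0
        es = np.linspace(sp.E_BETHE_MIN, e_hi, 100_001)
        inv = np.array([1.0 / electronic_stopping_power(e, PROTON, WATER)
                        for e in es])
        brute = np.trapezoid(inv, es) \
            + 2.0 * sp.E_BETHE_MIN / electronic_stopping_power(
                sp.E_BETHE_MIN, PROTON, WATER)
        assert csda_range(e_hi, PROTON, WATER) \
            == pytest.approx(brute, rel=1e-4)

    def test_proton_150mev_range_near_tabulated(self):
        # PSTAR-style CSDA range at 150 MeV is ~15.8 g/cm^2
        assert csda_range(150.0, PROTON, WATER) \
            == pytest.approx(15.8, rel=0.02)


class TestStoppingTable:
    def test_interpolation_matches_direct_evaluation(self):
        table = StoppingTable.build(PROTON, WATER)
        for e in (0.7, 23.0, 151.7, 432.1):
            assert table.stopping_at(np.array([e]))[0] \
                == pytest.approx(electronic_stopping_power(e, PROTON,
                                                           WATER),
                                 rel=2e-4)

    def test_range_interpolation_consistent(self):
        table = StoppingTable.build(PROTON, WATER)
        assert table.range_at(np.array([150.0]))[0] \
            == pytest.approx(csda_range(150.0, PROTON, WATER), rel=1e-3)

    def test_export_csv(self, tmp_path):
        from iondose.stopping import export_stopping_csv
        import pandas as pd
        out = tmp_path / "table.csv"
        export_stopping_csv(out, PROTON, WATER,
                            energies=np.array([10.0, 100.0]))
        df = pd.read_csv(out)
        assert list(df.columns) == ["E_MeV_u", "S_el_MeV_cm2_g",
                                    "S_restricted_MeV_cm2_g",
                                    "range_g_cm2"]
        assert (df["S_restricted_MeV_cm2_g"]
                <= df["S_el_MeV_cm2_g"] + 1e-12).all()
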