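"""The folding ensemble: enumeration, microstate energetics, exact
small-N oracle equivalence, closed-form limits, heat capacity and
melting-temperature estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_ensemble, random_contact_system
from electrofold.electrostatics import PairEnergyMatrix
from electrofold.structures import ContactMap
from electrofold.wsme import (Microstate, WSMEEnsemble, WSMEParameters,
                              calibrate_xi, ensemble_summary,
                              enumerate_microstates, heat_capacity_curve,
                              melting_temperature, microstate_free_energy)

R = 8.314


class TestEnumeration:
    @pytest.mark.parametrize("N,max_islands,expected", [
        (3, 1, 7),      # all but the 101 pattern
        (4, 2, 16),     # = 2^4, no 3-island pattern exists at N=4
        (1, 1, 2),
        (1, None, 2),
    ])
    def test_state_counts(self, N, max_islands, expected):
        assert sum(1 for _ in enumerate_microstates(N, max_islands)) == expected

    def test_counts_match_bit_enumeration_oracle(self):
        # island-count filter applied to raw bit patterns
        for N in (3, 4, 5, 6):
            for k in (1, 2):
                expected = 0
                for bits in range(2 ** N):
                    s = f"{bits:0{N}b}"
                    islands = len([g for g in s.split("0") if g])
                    if islands <= k:
                        expected += 1
                got = sum(1 for _ in enumerate_microstates(N, k))
                assert got == expected, (N, k)

    @settings(derandomize=True, max_examples=40)
    @given(N=st.integers(1, 9), k=st.integers(1, 2))
    def test_generated_states_are_valid_and_unique(self, N, k):
        seen = set()
        for state in enumerate_microstates(N, k):
            assert len(state.segments) <= k
            assert state.segments not in seen
            seen.add(state.segments)
            for (a, b), (a2, _) in zip(state.segments, state.segments[1:]):
                assert a2 >= b + 2  # disjoint, non-adjacent
            assert all(1 <= a <= b <= N for a, b in state.segments)

    def test_full_enumeration_guard(self):
        with pytest.raises(ValueError, match="refused"):
            list(enumerate_microstates(26, None))

    def test_invalid_segments_rejected(self):
        with pytest.raises(ValueError):
            Microstate(((1, 3), (4, 5)))  # adjacent islands
        with pytest.raises(ValueError):
            Microstate(((3, 2),))


class TestMicrostateFreeEnergy:
    def test_unfolded_state_is_reference_zero(self):
        cm = ContactMap({(1, 3): 2}, 5.0, 2, 3)
        g = microstate_free_energy(Microstate(()), cm, None,
                                   WSMEParameters(), 300.0)
        assert g == 0.0

    def test_solvation_term_vanishes_at_reference_temperature(self):
        p = WSMEParameters(xi=-500.0, dS_conf=-30.0, dCp_cont=-4.0, T_ref=385.0)
        cm = ContactMap({(1, 3): 2}, 5.0, 2, 3)
        el = PairEnergyMatrix({(1, 3): -1.5})
        g = microstate_free_energy(Microstate(((1, 3),)), cm, el, p, 385.0)
        expected = 2 * (-500.0) + 1000 * (-1.5) - 385.0 * 3 * (-30.0)
        assert g == pytest.approx(expected, rel=1e-12)

    def test_contact_alive_rule_by_hand(self):
        # state 111 has the (1,3) contact alive; state 110 does not
        p = WSMEParameters(xi=-300.0, dS_conf=-20.0, dCp_cont=0.0)
        cm = ContactMap({(1, 3): 1}, 5.0, 2, 3)
        g111 = microstate_free_energy(Microstate(((1, 3),)), cm, None, p, 310.0)
        g110 = microstate_free_energy(Microstate(((1, 2),)), cm, None, p, 310.0)
        assert g111 - g110 == pytest.approx(-300.0 + 310.0 * 20.0, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        cm = ContactMap({(1, 3): 1}, 5.0, 2, 3)
        with pytest.raises(ValueError):
            microstate_free_energy(Microstate(()), cm, None,
                                   WSMEParameters(), 0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("N,seed", [(8, 0), (10, 1), (12, 2)])
    def test_full_enumeration_matches_brute_force(self, N, seed):
        cm, electro, field = random_contact_system(N, seed)
        params = WSMEParameters()
        T = 315.0
        for fld in (None, field):
            log_Z, rho, logw_by_n = brute_force_ensemble(cm, electro, params,
                                                         T, fld)
            s = ensemble_summary(cm, PairEnergyMatrix(electro), params, T,
                                 max_islands=None, field=fld)
            assert s.log_Z == pytest.approx(log_Z, rel=1e-9)
            np.testing.assert_allclose(s.residue_prob, rho, rtol=1e-9)
            profile_expected = -R * T * logw_by_n / 1000.0
            profile_expected[0] = 0.0
            mask = np.isfinite(profile_expected)
            np.testing.assert_allclose(s.profile[mask],
                                       profile_expected[mask], rtol=1e-9,
                                       atol=1e-9)

    @pytest.mark.parametrize("max_islands", [1, 2])
    def test_island_engine_matches_filtered_brute_force(self, max_islands):
        cm, electro, field = random_contact_system(9, 5)
        params = WSMEParameters()
        T = 302.0
        log_Z, rho, logw_by_n = brute_force_ensemble(
            cm, electro, params, T, field, allowed_islands=max_islands)
        eng = WSMEEnsemble(cm, PairEnergyMatrix(electro), params, field=field,
                           max_islands=max_islands)
        s = eng.summary(T)
        assert s.log_Z == pytest.approx(log_Z, rel=1e-12)
        np.testing.assert_allclose(s.residue_prob, rho, rtol=1e-9)
        profile_expected = -R * T * logw_by_n / 1000.0
        profile_expected[0] = 0.0
        mask = np.isfinite(profile_expected)
        np.testing.assert_allclose(s.profile[mask], profile_expected[mask],
                                   rtol=1e-9, atol=1e-9)

    def test_nested_state_spaces_order_partition_functions(self):
        for seed in (3, 4):
            cm, electro, field = random_contact_system(10, seed)
            params = WSMEParameters()
            zs = [
                ensemble_summary(cm, PairEnergyMatrix(electro), params, 310.0,
                                 max_islands=mi, field=field,
                                 compute_profile=False).log_Z
                for mi in (1, 2, None)
            ]
            assert zs[0] <= zs[1] + 1e-12 <= zs[2] + 2e-12


class TestClosedFormLimits:
    def test_independent_site_limit(self):
        # xi = dCp = 0, no charges: each residue independent with weight
        # exp(dS_conf/R), so <rho_j> = w/(1+w)
        p = WSMEParameters(xi=0.0, dS_conf=-33.31, dCp_cont=0.0)
        cm = ContactMap({(1, 6): 1}, 5.0, 2, 6)
        s = ensemble_summary(cm, None, p, 300.0, max_islands=None)
        w = math.exp(p.dS_conf / R)
        np.testing.assert_allclose(s.residue_prob, w / (1 + w), rtol=1e-12)

    def test_profile_normalization_recovers_z(self):
        cm, electro, _ = random_contact_system(10, 8)
        for T in (280.0, 310.0, 340.0):
            s = ensemble_summary(cm, PairEnergyMatrix(electro),
                                 WSMEParameters(), T, max_islands=2)
            z_from_profile = np.log(
                np.sum(np.exp(-1000 * s.profile / (R * T) - s.log_Z))
            ) + s.log_Z
            assert z_from_profile == pytest.approx(s.log_Z, abs=1e-9)
            assert s.profile[0] == 0.0


def _two_state_system():
    """One all-or-nothing contact cluster with a sharp transition at
    the closed-form midpoint T* = c*xi/(2*dS_conf) = 320 K."""
    params = WSMEParameters(xi=-200.0, dS_conf=-1000.0, dCp_cont=0.0)
    cm = ContactMap({(1, 2): 3200}, 5.0, 1, 2)
    return params, cm, 320.0


class TestHeatCapacityAndMelting:
    def test_two_state_cp_peak_at_closed_form_midpoint(self):
        params, cm, t_star = _two_state_system()
        tg = np.arange(315.0, 325.0, 0.1)
        cp = heat_capacity_curve(cm, None, params, tg)
        assert tg[np.argmax(cp)] == pytest.approx(t_star, abs=0.2)

    def test_two_state_melting_temperature_closed_form(self):
        params, cm, t_star = _two_state_system()
        tg = np.arange(315.0, 325.0, 0.1)
        eng = WSMEEnsemble(cm, None, params, max_islands=2)
        assert melting_temperature(tg, eng.folding_curve(tg)) == pytest.approx(
            t_star, abs=0.2)

    def test_no_interactions_gives_flat_cp(self):
        p = WSMEParameters(xi=0.0, dS_conf=-33.31, dCp_cont=0.0)
        cm = ContactMap({(1, 5): 1}, 5.0, 2, 5)
        cp = heat_capacity_curve(cm, None, p, np.arange(280.0, 320.0, 1.0))
        assert np.abs(cp).max() < 1e-12

    def test_peak_height_converged_in_grid_step(self):
        params, cm, _ = _two_state_system()
        peak = []
        for step in (0.2, 0.1):
            tg = np.arange(316.0, 324.0, step)
            peak.append(heat_capacity_curve(cm, None, params, tg).max())
        assert abs(peak[1] - peak[0]) / peak[1] < 0.01

    def test_coarse_grid_warns(self):
        params, cm, _ = _two_state_system()
        with pytest.warns(UserWarning, match="coarser"):
            heat_capacity_curve(cm, None, params, np.arange(300.0, 340.0, 2.0))

    def test_uniform_stabilizing_field_raises_tm(self, small_scene):
        from electrofold.synthetic import TOY_WSME_PARAMS

        tg = np.arange(250.0, 400.0, 2.0)
        eng = WSMEEnsemble(small_scene.contacts, None, TOY_WSME_PARAMS)
        tm0 = melting_temperature(tg, eng.folding_curve(tg))
        stabilized = eng.with_field(np.full(small_scene.contacts.n_residues,
                                            -2000.0))
        tm1 = melting_temperature(tg, stabilized.folding_curve(tg))
        assert tm1 > tm0

    def test_flat_curve_raises_no_transition(self):
        tg = np.arange(280.0, 320.0, 1.0)
        with pytest.raises(ValueError, match="no transition"):
            melting_temperature(tg, np.full_like(tg, 0.3))


def test_calibration_recovers_target_melting_temperature(small_scene):
    from electrofold.synthetic import TOY_WSME_PARAMS

    p = calibrate_xi(small_scene.contacts, None, TOY_WSME_PARAMS,
                     target_tm=310.0)
    eng = WSMEEnsemble(small_scene.contacts, None, p)
    tg = np.arange(250.0, 400.0, 2.0)
    tm = melting_temperature(tg, eng.folding_curve(tg))
    assert tm == pytest.approx(310.0, abs=1.0)
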