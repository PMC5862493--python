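import math

import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from photogain.morphology import MorphologySpec, generate_arbor
from photogain.opsins import (OpsinState, available_presets,
                              conducting_fraction, decorate_inverse_area,
                              load_preset, photocurrent, rate_matrix,
                              steady_state_occupancy, step_occupancy,
                              voltage_factor, xnphr_condition)

PHI_GRID = (0.002, 0.02, 0.2, 2.0)


@pytest.fixture(scope="module")
def chr2():
    return load_preset("chr2_6state")


@pytest.fixture(scope="module")
def nphr():
    return load_preset("nphr_6state")


class TestRateMatrix:
    def test_all_presets_load(self):
        names = available_presets()
        assert {"chr2_3state", "chr2_4state", "chr2_6state",
                "nphr_6state"} <= set(names)
        for n in names:
            m = load_preset(n)
            assert m.n_states >= 3

    @pytest.mark.parametrize("phi", (0.0,) + PHI_GRID)
    def test_rows_sum_to_zero(self, chr2, phi):
        Q = rate_matrix(chr2, phi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()

    def test_dark_state_absorbing_without_light(self, chr2):
        ss = steady_state_occupancy(chr2, 0.0)
        assert ss.occupancy[chr2.dark_state_index] == pytest.approx(1.0)

    def test_linear_preset_doubles_light_gated_rates(self):
        m = load_preset("chr2_3state")
        q1 = rate_matrix(m, 0.1)
        q2 = rate_matrix(m, 0.2)
        # light-gated C->O entry doubles, dark transitions unchanged
        c, o, d = 0, 1, 2
        assert q2[c, o] == pytest.approx(2 * q1[c, o])
        assert q2[o, d] == q1[o, d]
        assert q2[d, c] == q1[d, c]

    def test_negative_irradiance_rejected(self, chr2):
        with pytest.raises(ValueError):
            rate_matrix(chr2, -1.0)


class TestOccupancyDynamics:
    def test_zero_generator_is_identity(self, chr2):
        state = chr2.dark_occupancy()
        out = step_occupancy(state, np.zeros((6, 6)), 0.025)
        assert np.array_equal(out.occupancy, state.occupancy)

    def test_step_matches_ode_integration(self, chr2):
        """One dt=0.025 ms step against an independent stiff ODE solve."""
        Q = rate_matrix(chr2, 0.2)
        p0 = chr2.dark_occupancy().occupancy
        stepped = step_occupancy(OpsinState(p0), Q, 0.025).occupancy
        sol = scipy.integrate.solve_ivp(
            lambda t, p: p @ Q, (0.0, 0.025), p0, rtol=1e-10, atol=1e-12)
        assert np.abs(stepped - sol.y[:, -1]).max() < 1e-6

    def test_conservation_over_many_steps(self, chr2):
        Q = rate_matrix(chr2, 0.02)
        state = chr2.dark_occupancy()
        for _ in range(100_000):
            state = step_occupancy(state, Q, 0.025)
        assert abs(state.occupancy.sum() - 1.0) < 1e-9
        assert (state.occupancy >= -1e-12).all()

    @pytest.mark.parametrize("phi", PHI_GRID)
    def test_steady_state_matches_long_run(self, chr2, phi):
        Q = rate_matrix(chr2, phi)
        P = scipy.linalg.expm(Q * 0.025)
        long_run = chr2.dark_occupancy().occupancy @ np.linalg.matrix_power(
            P, 800_000)  # 20 s
        ss = steady_state_occupancy(chr2, phi).occupancy
        assert np.abs(long_run - ss).max() < 1e-6

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(dt=st.floats(1e-3, 1.0), phi=st.floats(0.0, 2.0),
           seed=st.integers(0, 10_000))
    def test_occupancy_stays_probability_vector(self, chr2, dt, phi, seed):
        rng = np.random.default_rng(seed)
        p0 = rng.dirichlet(np.ones(chr2.n_states))
        state = OpsinState(p0)
        Q = rate_matrix(chr2, phi)
        for _ in range(20):
            state = step_occupancy(state, Q, dt)
        assert abs(state.occupancy.sum() - 1.0) < 1e-9
        assert (state.occupancy >= -1e-12).all()


class TestPhotocurrent:
    def test_zero_when_closed(self, chr2):
        assert photocurrent(chr2, chr2.dark_occupancy(), -65.0, 100.0) == 0.0

    def test_zero_at_reversal(self, chr2, nphr):
        ss = steady_state_occupancy(chr2, 0.2)
        e_rev = chr2.voltage_fn["e_rev_mV"]
        assert photocurrent(chr2, ss, e_rev, 100.0) == pytest.approx(0.0)
        ssn = steady_state_occupancy(nphr, 0.2)
        assert photocurrent(nphr, ssn, -400.0, 100.0) == pytest.approx(0.0)

    def test_hand_evaluated_value(self, chr2):
        """i = 1e-5 * scale * g_max * psi_ss * f(-65), assembled by hand."""
        phi, v, scale = 0.02, -65.0, 62.83
        Q = rate_matrix(chr2, phi)
        ns = scipy.linalg.null_space(Q.T)
        pss = ns[:, 0] / ns[:, 0].sum()
        psi = float(chr2.open_state_weights @ pss)
        u = 40.0
        f = u * (1.0 - math.exp(-(v - 0.0) / u))
        expected = 1e-5 * scale * chr2.g_max * psi * f
        got = photocurrent(chr2, steady_state_occupancy(chr2, phi), v, scale)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got < 0  # depolarizing: inward below reversal

    def test_nphr_is_hyperpolarizing(self, nphr):
        ss = steady_state_occupancy(nphr, 0.2)
        assert photocurrent(nphr, ss, -65.0, 62.83) > 0

    @pytest.mark.parametrize("preset", ["chr2_6state", "nphr_6state",
                                        "chr2_4state", "chr2_3state"])
    def test_monotone_in_irradiance_at_steady_state(self, preset):
        m = load_preset(preset)
        mags = []
        for phi in (0.002, 0.01, 0.05, 0.2, 1.0, 2.0):
            ss = steady_state_occupancy(m, phi)
            mags.append(abs(photocurrent(m, ss, -65.0, 62.83)))
        assert all(a <= b + 1e-15 for a, b in zip(mags, mags[1:]))


class TestPlacement:
    def test_inverse_area_scale_ratio(self):
        arbor = generate_arbor(MorphologySpec(1, 1, 1))
        chr2 = load_preset("chr2_6state")
        placement = decorate_inverse_area(arbor, chr2, 62.83)
        # soma area is 5x a section's area -> its scale is 5x smaller
        by_id = dict(zip(placement.section_ids.tolist(),
                         placement.scale.tolist()))
        assert by_id[1] / by_id[0] == pytest.approx(
            math.pi * 10 * 10 / (math.pi * 0.4 * 50))

    def test_equal_effective_area_everywhere(self, bipolar_arbor):
        model = load_preset("chr2_6state")
        placement = decorate_inverse_area(bipolar_arbor, model, 10.0)
        areas = np.array([bipolar_arbor.section(i).lateral_area
                          for i in placement.section_ids])
        eff = placement.scale * areas
        assert np.abs(eff - 10.0).max() < 1e-12

    def test_total_current_scales_with_compartment_count(self):
        model = load_preset("chr2_6state")
        ss = steady_state_occupancy(model, 0.2)
        totals = []
        for n_l in (2, 3, 4):
            arbor = generate_arbor(MorphologySpec(2, 2, n_l))
            placement = decorate_inverse_area(arbor, model, 5.0)
            per = photocurrent(model, ss, -65.0, 5.0)
            totals.append((len(placement.section_ids), per
                           * len(placement.section_ids)))
        for (n1, t1), (n2, t2) in zip(totals, totals[1:]):
            assert t2 / t1 == pytest.approx(n2 / n1)

    def test_zero_g_ref_rejected(self, bipolar_arbor):
        with pytest.raises(ValueError):
            decorate_inverse_area(bipolar_arbor,
                                  load_preset("chr2_6state"), 0.0)


class TestXnphr:
    @pytest.mark.parametrize("base, x, expected", [
        (0.02, 0.0, (0.02, 0.0)),
        (0.02, 4.0, (0.02, 0.08)),
        (0.2, 1.0, (0.2, 0.2)),
        (0.02, 0.25, (0.02, 0.005)),
    ])
    def test_irradiance_pairs(self, base, x, expected):
        chr2_irr, nphr_irr = xnphr_condition(base, x)
        assert (chr2_irr, nphr_irr) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            xnphr_condition(-0.1, 1.0)
        with pytest.raises(ValueError):
            xnphr_condition(0.1, -1.0)
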