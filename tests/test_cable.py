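import math

import numpy as np
import pytest

from photogain.cable import (CurrentInjection, HHParams, IlluminationField,
                             OpsinLight, PassiveParams, Protocol, SynapseSpec,
                             build_system, calibrate_synaptic_weights,
                             detect_spikes, make_illumination, partial_mask,
                             resting_potential, run, steady_state_passive,
                             step)
from photogain.morphology import MorphologySpec, generate_arbor
from photogain.opsins import decorate_inverse_area, load_preset


def dense_backward_euler(system, v, dt, inj=None):
    """Independent dense-matrix backward-Euler step for oracle comparison."""
    n = system.n
    A = np.diag(system.cap / dt + system.g_pas)
    b = system.cap / dt * v + system.g_pas * system.e_pas
    for i in range(1, n):
        p = system.parent[i]
        g = system.g_ax[i]
        A[i, i] += g
        A[p, p] += g
        A[i, p] -= g
        A[p, i] -= g
    for comp, amp in (inj or {}).items():
        b[comp] += amp
    return np.linalg.solve(A, b)


class TestPassiveSolver:
    def test_resting_stability(self, passive_bipolar_system):
        res = run(passive_bipolar_system, Protocol(), 1000.0)
        assert abs(res.soma_v[-1] - res.soma_v[0]) < 0.1
        assert abs(res.soma_v[-1] - (-75.0)) < 1e-9

    def test_two_compartment_steady_state_matches_hand_solution(self):
        """Soma + one section under injection vs explicit 2x2 circuit."""
        arbor = generate_arbor(MorphologySpec(1, 1, 1))
        passive = PassiveParams()
        system = build_system(arbor, passive=passive)
        amp = 0.01  # nA at the dendrite
        v = steady_state_passive(system, {1: amp})

        # hand-built 2x2: conductances in uS from first principles
        a_soma = math.pi * 10 * 10 * 1e-8      # cm^2
        a_dend = math.pi * 0.4 * 50 * 1e-8
        g_s = passive.g_pass * a_soma * 1e6
        g_d = passive.g_pass * a_dend * 1e6
        r_ax = passive.axial_resistivity * (
            (5e-4) / (math.pi * (5e-4) ** 2)
            + (25e-4) / (math.pi * (0.2e-4) ** 2))
        g_ax = 1e6 / r_ax
        A = np.array([[g_s + g_ax, -g_ax], [-g_ax, g_d + g_ax]])
        b = np.array([g_s * -75.0, g_d * -75.0 + amp])
        expected = np.linalg.solve(A, b)
        assert np.abs(v - expected).max() < 1e-8

    def test_implicit_step_equals_dense_solve_on_10_comp_tree(self):
        arbor = generate_arbor(MorphologySpec(3, 2, 2))  # 9 sections + soma
        system = build_system(arbor)
        assert system.n == 10
        system.reset(-70.0)  # away from rest so dynamics are non-trivial
        dt = 0.025
        inj = {system.comp_of(arbor.terminals()[0].id): 0.05}
        for _ in range(5):
            expected = dense_backward_euler(system, system.v.copy(), dt, inj)
            got = step(system, dt, inj)
            assert np.abs(got - expected).max() < 1e-10

    def test_cosh_cable_profile(self):
        """Uniform 21-compartment sealed cable vs analytic steady state."""
        spec = MorphologySpec(1, 1, 20, soma_length=50.0, soma_diameter=0.4)
        arbor = generate_arbor(spec)
        passive = PassiveParams()
        system = build_system(arbor, passive=passive)
        amp = 0.001
        terminal = arbor.terminals()[0].id
        v = steady_state_passive(system, {terminal: amp})
        dv = v - (-75.0)

        d_cm, g, ra = 0.4e-4, passive.g_pass, passive.axial_resistivity
        lam = math.sqrt(d_cm / (4.0 * g * ra))          # cm
        r_i = ra / (math.pi * (d_cm / 2) ** 2)          # Ohm/cm
        ell = 21 * 50e-4                                # cm
        # x measured from the injected end; compartment centers
        for k in range(21):
            comp = system.n - 1 - k
            x = (k + 0.5) * 50e-4
            expected = (amp * 1e-9) * r_i * lam * (
                math.cosh((ell - x) / lam) / math.sinh(ell / lam)) * 1e3
            assert dv[comp] == pytest.approx(expected, rel=0.01)

    def test_halving_dt_leaves_steady_state(self, passive_bipolar_system):
        sysm = passive_bipolar_system
        inj = [CurrentInjection(1, 0.02, 0.0)]
        va = run(sysm, Protocol(injections=inj), 600.0, dt=0.05).soma_v[-1]
        vb = run(sysm, Protocol(injections=inj), 600.0, dt=0.025).soma_v[-1]
        assert abs(va - vb) < 1e-6

    def test_no_driving_force_means_no_dynamics(self, bipolar_arbor):
        hh = HHParams(ena=-75.0, ek=-75.0, el=-75.0)
        system = build_system(bipolar_arbor, hh_soma=hh)
        res = run(system, Protocol(), 100.0)
        assert np.abs(res.soma_v - (-75.0)).max() < 1e-10


class TestSuperposition:
    @pytest.fixture()
    def passive_lit_system(self, bipolar_arbor):
        # pump-type (current-source) photocurrents: f(V) constant
        chr2 = load_preset("chr2_6state",
                           voltage_fn={"form": "constant", "drive_mV": -65.0})
        nphr = load_preset("nphr_6state",
                           voltage_fn={"form": "constant", "drive_mV": 335.0})
        placements = [(chr2, decorate_inverse_area(bipolar_arbor, chr2, 1.0)),
                      (nphr, decorate_inverse_area(bipolar_arbor, nphr, 1.0))]
        return build_system(bipolar_arbor, opsin_placements=placements)

    @staticmethod
    def _field(system, irr, x):
        names = system.opsin_names
        return IlluminationField({
            names[0]: OpsinLight(irr, 100.0, 900.0),
            names[1]: OpsinLight(irr * x, 100.0, 900.0)})

    def test_current_source_photocurrent_superposes_exactly(
            self, passive_lit_system, bipolar_arbor):
        sysm = passive_lit_system
        site = bipolar_arbor.terminals()[0].id
        inj = [CurrentInjection(site, 0.02, 100.0, 900.0)]
        ill = self._field(sysm, 0.02, 1.0)
        v_rest = run(sysm, Protocol(), 900.0).soma_v
        v_inj = run(sysm, Protocol(injections=inj), 900.0).soma_v
        v_lit = run(sysm, Protocol(illumination=ill), 900.0).soma_v
        v_both = run(sysm, Protocol(injections=inj, illumination=ill),
                     900.0).soma_v
        lhs = v_both - v_rest
        rhs = (v_inj - v_rest) + (v_lit - v_rest)
        rel = np.abs(lhs - rhs).max() / np.abs(lhs).max()
        assert rel < 1e-6

    def test_conductance_photocurrent_superposes_approximately(
            self, bipolar_arbor):
        """Conductance-based opsins superpose only approximately: the
        injection changes the local driving force of the photocurrent, so
        linearity holds in the small-signal regime and degrades with
        amplitude."""
        chr2 = load_preset("chr2_6state")
        nphr = load_preset("nphr_6state")
        placements = [(chr2, decorate_inverse_area(bipolar_arbor, chr2, 0.05)),
                      (nphr, decorate_inverse_area(bipolar_arbor, nphr, 0.05))]
        sysm = build_system(bipolar_arbor, opsin_placements=placements)
        site = bipolar_arbor.terminals()[0].id
        inj = [CurrentInjection(site, 0.002, 100.0, 900.0)]
        ill = self._field(sysm, 0.02, 1.0)
        v_rest = run(sysm, Protocol(), 900.0).soma_v
        v_inj = run(sysm, Protocol(injections=inj), 900.0).soma_v
        v_lit = run(sysm, Protocol(illumination=ill), 900.0).soma_v
        v_both = run(sysm, Protocol(injections=inj, illumination=ill),
                     900.0).soma_v
        lhs = v_both - v_rest
        rhs = (v_inj - v_rest) + (v_lit - v_rest)
        rel = np.abs(lhs - rhs).max() / np.abs(lhs).max()
        assert rel < 0.05


class TestActiveSoma:
    def test_isolated_hh_soma_fires_repetitively(self, soma_only_arbor):
        system = build_system(soma_only_arbor, hh_soma=HHParams())
        res = run(system, Protocol(
            injections=[CurrentInjection("soma", 0.1, 100.0, 1100.0)]),
            1200.0)
        sustained = res.spike_times[(res.spike_times > 300)
                                    & (res.spike_times < 1100)]
        assert len(sustained) > 20

    def test_spike_counts_stable_under_dt_refinement(self):
        """Volley-driven spiking: halving dt changes counts by <= 1."""
        arbor = generate_arbor(MorphologySpec(2, 2, 4))
        system = build_system(
            arbor, passive=PassiveParams(axial_resistivity=150.0),
            hh_soma=HHParams())
        times = np.arange(100.0, 9900.0, 120.0)
        sites = [s.id for s in arbor.terminals()[:6]]
        syns = [SynapseSpec(s, 0.02, tau=2.0, event_times=times)
                for s in sites]
        counts = []
        for dt in (0.025, 0.0125):
            res = run(system, Protocol(synapses=syns), 10_000.0, dt=dt)
            counts.append(len(res.spike_times))
        assert counts[0] > 50
        assert abs(counts[0] - counts[1]) <= 1

    def test_run_is_deterministic(self, hh_bipolar_system):
        proto = Protocol(injections=[CurrentInjection(1, 0.3, 50.0, 450.0)])
        a = run(hh_bipolar_system, proto, 500.0)
        b = run(hh_bipolar_system, proto, 500.0)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.soma_v, b.soma_v)

    def test_zero_duration_protocol(self, hh_bipolar_system):
        res = run(hh_bipolar_system, Protocol(), 0.0)
        assert res.t.size == 0
        assert res.spike_times.size == 0

    def test_unknown_record_site(self, hh_bipolar_system):
        with pytest.raises(KeyError):
            run(hh_bipolar_system, Protocol(), 10.0, record_sites=[4242])


class TestSpikeDetection:
    def test_flat_trace_has_no_spikes(self):
        v = np.full(1000, -70.0)
        assert detect_spikes(v, 0.025).size == 0

    def test_single_crossing(self):
        v = np.full(100, -70.0)
        v[50:] = 10.0
        st = detect_spikes(v, 0.1, threshold_mV=0.0)
        assert st.size == 1
        assert st[0] == pytest.approx(50 * 0.1)

    def test_refractory_merge(self):
        dt = 0.5
        v = np.full(40, -70.0)
        v[10] = 10.0   # crossing at 5.0 ms
        v[12] = 10.0   # crossing at 6.0 ms, inside 2 ms refractory
        st = detect_spikes(v, dt, refractory_ms=2.0)
        assert st.size == 1


class TestIllumination:
    def test_uniform_when_ungraded(self, bipolar_arbor):
        field = IlluminationField({"chr2-6state": OpsinLight(0.5)})
        phi = make_illumination(bipolar_arbor, field)["chr2-6state"]
        assert set(phi.values()) == {0.5}

    def test_full_gradient_zeroes_the_deepest(self):
        arbor = generate_arbor(MorphologySpec(1, 1, 3))
        field = IlluminationField(
            {"o": OpsinLight(1.0, gradient=1.0, light_from="distal")})
        phi = make_illumination(arbor, field)["o"]
        # soma is deepest from the illuminated (distal) surface
        assert phi[arbor.soma.id] == pytest.approx(0.0)
        assert phi[arbor.terminals()[0].id] == pytest.approx(1.0)

    def test_half_gradient_midpoint(self):
        arbor = generate_arbor(MorphologySpec(1, 1, 3))
        field = IlluminationField(
            {"o": OpsinLight(1.0, gradient=0.5, coverage=[1, 2, 3],
                             light_from="distal")})
        phi = make_illumination(arbor, field)["o"]
        # covered mids: 25, 75, 125 -> section 2 has depth_norm 0.5
        assert phi[2] == pytest.approx(0.75)
        assert phi[arbor.soma.id] == 0.0  # uncovered

    def test_partial_mask_full_and_half(self, bipolar_arbor):
        full = partial_mask(bipolar_arbor, [0, 1], include_soma=False)
        assert len(full) == len(bipolar_arbor)
        half = partial_mask(bipolar_arbor, [0], include_soma=False)
        assert len(half) == len(bipolar_arbor) // 2
        with pytest.raises(KeyError):
            partial_mask(bipolar_arbor, [7])

    def test_empty_mask_equals_darkness(self, bipolar_arbor):
        chr2 = load_preset("chr2_6state")
        placements = [(chr2, decorate_inverse_area(bipolar_arbor, chr2, 1.0))]
        sysm = build_system(bipolar_arbor, opsin_placements=placements)
        ill = IlluminationField({chr2.name: OpsinLight(0.5, 10.0, 90.0,
                                                       coverage=[])})
        lit = run(sysm, Protocol(illumination=ill), 100.0).soma_v
        dark = run(sysm, Protocol(), 100.0).soma_v
        assert np.array_equal(lit, dark)


class TestWeightCalibration:
    @staticmethod
    def _monotone_probe(w):
        # saturating monotone response: 0 -> 40 Hz
        return 40.0 * w / (w + 0.01)

    def test_bisection_reaches_target(self):
        res = calibrate_synaptic_weights(self._monotone_probe, 20.0,
                                         bracket=(1e-4, 1.0), tol_hz=1.0)
        assert res.feasible
        assert abs(self._monotone_probe(res.weight) - 20.0) <= 1.0

    def test_target_met_at_lower_edge(self):
        res = calibrate_synaptic_weights(lambda w: 10.0, 10.0,
                                         bracket=(1e-3, 1.0))
        assert res.feasible
        assert res.weight == pytest.approx(1e-3)

    def test_flat_zero_response_is_infeasible(self):
        res = calibrate_synaptic_weights(lambda w: 0.0, 20.0,
                                         bracket=(1e-4, 1.0))
        assert not res.feasible
        assert res.weight is None
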