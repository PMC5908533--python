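"""Euler integration, spike handling and trial orchestration."""

import numpy as np
import pytest

from wavepatch import (
    LatticeGeometry,
    ModelParameters,
    SimulationConfig,
    StimulusProtocol,
    build_kernels,
    initialize_state,
    run_sweep,
    run_trial,
    step,
)
from wavepatch.simulate import pairwise_increments, _deposit


def _quiet_config(n=12, **kw):
    defaults = dict(
        geometry=LatticeGeometry(n=n),
        params=ModelParameters(cutoff=min(5, n // 2 - 1)),
        protocol=StimulusProtocol(centre=(n // 2, n // 2), i_background=0.0),
        duration_ms=100.0,
        burn_in_ms=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestInitialState:
    def test_potentials_uniform_between_reset_and_threshold(self):
        geom, p = LatticeGeometry(n=60), ModelParameters()
        st = initialize_state(geom, p, seed=3)
        assert st.v.min() >= p.v_reset and st.v.max() < p.v_th
        assert np.all(st.g_e == 0) and np.all(st.g_i == 0)
        assert np.all(st.refractory_remaining == 0)

    def test_same_seed_reproduces_grid(self):
        geom, p = LatticeGeometry(n=40), ModelParameters()
        a = initialize_state(geom, p, seed=11)
        b = initialize_state(geom, p, seed=11)
        np.testing.assert_array_equal(a.v, b.v)


class TestSingleStep:
    def test_leak_relaxation_single_step(self):
        # uncoupled neuron at -60 mV with no drive: dV = -(V-V_L) dt / tau_m
        cfg = _quiet_config()
        kernels = build_kernels(cfg.params)
        st = initialize_state(cfg.geometry, cfg.params, seed=0)
        st.v[:] = -60.0
        step(st, kernels, cfg.protocol, cfg.params, cfg.geometry)
        np.testing.assert_allclose(st.v, -60.025, rtol=1e-12)

    def test_conductance_euler_decay(self):
        cfg = _quiet_config()
        kernels = build_kernels(cfg.params)
        st = initialize_state(cfg.geometry, cfg.params, seed=0)
        st.v[:] = cfg.params.v_leak
        st.g_e[:] = 1.0
        step(st, kernels, cfg.protocol, cfg.params, cfg.geometry)
        np.testing.assert_allclose(st.g_e, 0.975, rtol=1e-12)  # 1 - dt/tau_E

    def test_threshold_reset_and_refractory_silence(self):
        cfg = _quiet_config()
        p = cfg.params
        kernels = build_kernels(p)
        st = initialize_state(cfg.geometry, p, seed=0)
        st.v[:] = p.v_leak
        st.v[3, 3] = p.v_th + 0.5  # will fire on the first step
        spikes = []
        for _ in range(int(p.tau_ref / p.dt) + 2):
            step(st, kernels, cfg.protocol, p, cfg.geometry, spike_out=spikes)
            if len(spikes) == 1:
                assert st.v[3, 3] == p.v_reset
        assert [s[1:] for s in spikes] == [(3, 3)]

    def test_quiescent_network_relaxes_monotonically_to_leak(self):
        cfg = _quiet_config()
        kernels = build_kernels(cfg.params)
        st = initialize_state(cfg.geometry, cfg.params, seed=5)
        prev = st.v.copy()
        for _ in range(4000):  # 200 ms = 10 membrane time constants
            step(st, kernels, cfg.protocol, cfg.params, cfg.geometry)
            assert np.all(st.v <= prev + 1e-12)
            prev = st.v.copy()
        np.testing.assert_allclose(st.v, cfg.params.v_leak, atol=0.1)


class TestCouplingEquivalence:
    def test_stencil_deposit_equals_pairwise_sum(self):
        # random spike pattern on a 12x12 lattice: translation-invariant
        # accumulation must equal the brute-force afferent double sum exactly
        rng = np.random.default_rng(42)
        n = 12
        p = ModelParameters(cutoff=5)
        kernels = build_kernels(p)
        coords = np.argwhere(rng.random((n, n)) < 0.2)
        inh = (coords[:, 0] % 2 == 1) & (coords[:, 1] % 2 == 1)
        g_e = np.zeros((n, n))
        g_i = np.zeros((n, n))
        _deposit(g_e, coords[~inh], kernels.patch_e, n)
        _deposit(g_i, coords[inh], kernels.patch_i, n)
        ref_e, ref_i = pairwise_increments(coords[~inh], coords[inh], p, n)
        # summation order differs between the two routes, so allow round-off
        np.testing.assert_allclose(g_e, ref_e, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(g_i, ref_i, rtol=1e-12, atol=1e-15)

    def test_wrapped_stencil_on_tiny_lattice(self):
        # lattice smaller than the stencil: wrap-around must still accumulate
        n = 8
        p = ModelParameters(cutoff=5)
        kernels = build_kernels(p)
        g = np.zeros((n, n))
        _deposit(g, np.array([[0, 0]]), kernels.patch_e, n)
        ref, _ = pairwise_increments(np.array([[0, 0]]), np.empty((0, 2)), p, n)
        np.testing.assert_allclose(g, ref, rtol=1e-13)


class TestTrials:
    def test_no_drive_no_spikes(self):
        cfg = _quiet_config(duration_ms=200.0)
        rec = run_trial(cfg, seed=1)
        assert len(rec.spikes) == 0

    def test_isolated_lif_rate_matches_closed_form(self):
        # W_E = W_I = 0, I_0 = 0.4 nA: ISI = tau_ref + tau_m ln((Vinf-V_R)/(Vinf-V_th))
        p = ModelParameters(w_e=1e-30, w_i=1e-30)
        cfg = SimulationConfig(
            geometry=LatticeGeometry(n=6),
            params=p,
            protocol=StimulusProtocol(centre=(3, 3), i_background=0.4),
            duration_ms=3000.0,
            burn_in_ms=500.0,
        )
        rec = run_trial(cfg, seed=2)
        v_inf = p.v_leak + 0.4 / p.g_l * 1e3
        isi = p.tau_ref + p.tau_m * np.log((v_inf - p.v_reset) / (v_inf - p.v_th))
        expected = 1000.0 / isi
        sp = rec.spikes_after_burn_in()
        rate = len(sp) / (36 * 2.5)
        assert rate == pytest.approx(expected, rel=0.02)

    def test_refractory_period_respected_in_all_spike_trains(self):
        p = ModelParameters(w_e=1e-30, w_i=1e-30)
        cfg = SimulationConfig(
            geometry=LatticeGeometry(n=6),
            params=p,
            protocol=StimulusProtocol(centre=(3, 3), i_background=0.5),
            duration_ms=500.0,
            burn_in_ms=0.0,
        )
        rec = run_trial(cfg, seed=3)
        df = rec.spikes.sort_values("time_ms")
        for _, g in df.groupby(["x", "y"]):
            isis = np.diff(g.time_ms.values)
            assert np.all(isis >= p.tau_ref - 1e-9)

    def test_identical_seed_bit_identical_recording(self):
        cfg = _quiet_config(
            protocol=StimulusProtocol(centre=(6, 6), i_background=0.45),
            duration_ms=300.0,
        )
        a = run_trial(cfg, seed=9, probes=[(2, 2)])
        b = run_trial(cfg, seed=9, probes=[(2, 2)])
        assert a.spikes.equals(b.spikes)
        np.testing.assert_array_equal(a.probe_traces["v"], b.probe_traces["v"])

    def test_sweep_assigns_distinct_reproducible_seeds(self):
        cfg = _quiet_config(
            protocol=StimulusProtocol(centre=(6, 6), i_background=0.45),
            duration_ms=150.0,
        )
        out = run_sweep(cfg, strengths=[0.0], n_trials=2, seed_base=50)
        assert {r.seed for r in out.values()} == {50, 51}
        again = run_sweep(cfg, strengths=[0.0], n_trials=2, seed_base=50)
        for key in out:
            assert out[key].spikes.equals(again[key].spikes)

    def test_empty_strength_list_rejected(self):
        with pytest.raises(ValueError):
            run_sweep(_quiet_config(), strengths=[], n_trials=1, seed_base=0)
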