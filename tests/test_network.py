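"""Unit tests of the LIF network: wiring, stepping, drive, single-neuron runs."""

import numpy as np
import pytest

from tdcsnet import (
    ConfigurationError,
    NetworkConfig,
    NetworkState,
    build_static_wiring,
    free_membrane_potential,
    poisson_drive,
    simulate_single_neuron,
    step,
)
from tdcsnet.network import LUT_BITS, poisson_count_lut
from tdcsnet._kernel import run_chunk


def edges_of(wiring, n_total):
    out = []
    for j in range(n_total):
        for e in range(wiring.indptr[j], wiring.indptr[j + 1]):
            out.append((j, int(wiring.idx[e]), float(wiring.w[e])))
    return out


class TestStaticWiring:
    def test_zero_probability_gives_empty_block(self):
        cfg = NetworkConfig(n_e=20, n_i=5, gamma_ie=0.0, gamma_ei=0.3,
                            gamma_ii=0.3, r_ext=0.0)
        w = build_static_wiring(cfg, seed=0)
        # no I -> E edges: every target of an inhibitory source is inhibitory
        for j, tgt, _ in edges_of(w, cfg.n_total):
            if j >= cfg.n_e:
                assert tgt >= cfg.n_e

    def test_full_probability_gives_complete_digraph_without_autapses(self):
        cfg = NetworkConfig(n_e=2, n_i=3, gamma_ei=0.0, gamma_ie=0.0,
                            gamma_ii=1.0, r_ext=0.0)
        w = build_static_wiring(cfg, seed=1)
        ii = [(j, t) for j, t, _ in edges_of(w, cfg.n_total)
              if j >= cfg.n_e and t >= cfg.n_e]
        assert len(ii) == 3 * 2  # ordered pairs among 3 neurons, no self-loops
        assert all(j != t for j, t in ii)

    def test_synapse_count_matches_binomial_statistics(self):
        cfg = NetworkConfig(n_e=10_000, n_i=2_500, gamma_ie=0.0, gamma_ii=0.0)
        w = build_static_wiring(cfg, seed=7)
        n_pairs = cfg.n_e * cfg.n_i
        mean = cfg.gamma_ei * n_pairs
        sd = np.sqrt(n_pairs * cfg.gamma_ei * (1 - cfg.gamma_ei))
        assert abs(w.n_static_synapses - mean) < 5 * sd

    def test_reproducible_from_seed(self):
        cfg = NetworkConfig(n_e=30, n_i=10)
        w1 = build_static_wiring(cfg, seed=3)
        w2 = build_static_wiring(cfg, seed=3)
        assert np.array_equal(w1.idx, w2.idx)
        assert np.array_equal(w1.indptr, w2.indptr)

    def test_ee_block_starts_empty(self):
        cfg = NetworkConfig(n_e=10, n_i=3)
        assert build_static_wiring(cfg, seed=0).A.sum() == 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(gamma_ei=1.5)


class TestStep:
    def _state(self, cfg, params, seed=0):
        return NetworkState.initial(cfg, params, seed)

    def test_pure_exponential_decay_over_one_time_constant(self, neuron):
        cfg = NetworkConfig(n_e=1, n_i=0, r_ext=0.0, dt=10.0, delay=10.0)
        w = build_static_wiring(cfg, seed=0)
        st = self._state(cfg, neuron)
        st.V[0] = 10.0
        step(st, w, cfg, neuron, ext_counts=np.zeros(1, dtype=int))
        assert st.V[0] == pytest.approx(10.0 * np.exp(-1.0), rel=1e-12)

    def test_arriving_excitatory_spike_jumps_by_j_e(self, neuron, tiny_net):
        w = build_static_wiring(tiny_net, seed=0)
        st = self._state(tiny_net, neuron)
        st.pending[st.slot, 0] = tiny_net.j_e
        step(st, w, tiny_net, neuron, ext_counts=np.zeros(6, dtype=int))
        assert st.V[0] == pytest.approx(0.1)

    def test_subthreshold_polarization_converges_without_spiking(self, neuron):
        cfg = NetworkConfig(n_e=1, n_i=0, r_ext=0.0, dt=1.0, delay=1.0)
        w = build_static_wiring(cfg, seed=0)
        st = self._state(cfg, neuron)
        st.delta_v[0] = 1.2
        spikes = []
        for _ in range(200):
            spikes.extend(step(st, w, cfg, neuron, ext_counts=np.zeros(1, int)))
        assert st.V[0] == pytest.approx(1.2, abs=1e-8)
        assert not spikes

    def test_threshold_crossing_resets_and_enters_refractoriness(self, neuron, tiny_net):
        w = build_static_wiring(tiny_net, seed=0)
        st = self._state(tiny_net, neuron)
        st.pending[st.slot, 0] = 25.0  # strong compound input
        spikers = step(st, w, tiny_net, neuron, ext_counts=np.zeros(6, int))
        assert list(spikers) == [0]
        assert st.V[0] == neuron.v_reset
        # clamped at reset while refractory even under further input
        st.pending[st.slot, 0] = 25.0
        spikers = step(st, w, tiny_net, neuron, ext_counts=np.zeros(6, int))
        assert list(spikers) == []
        assert st.V[0] == neuron.v_reset

    def test_spike_delivery_respects_delay(self, neuron):
        # one E neuron wired to one I neuron (p = 1): spike arrives delay later
        cfg = NetworkConfig(n_e=1, n_i=1, gamma_ei=1.0, gamma_ie=0.0,
                            gamma_ii=0.0, r_ext=0.0, dt=0.5, delay=1.5)
        w = build_static_wiring(cfg, seed=0)
        st = self._state(cfg, neuron)
        st.V[0] = 25.0  # crosses threshold on first step
        step(st, w, cfg, neuron, ext_counts=np.zeros(2, int))
        v_i = []
        for _ in range(4):
            step(st, w, cfg, neuron, ext_counts=np.zeros(2, int))
            v_i.append(st.V[1])
        # delay = 3 steps: arrival on the third step after emission
        assert v_i[0] == 0.0 and v_i[1] == 0.0
        assert v_i[2] == pytest.approx(cfg.j_e)


class TestPoissonDrive:
    def test_zero_rate_gives_zero_counts(self):
        rng = np.random.default_rng(0)
        assert poisson_drive(0.0, 0.1, 100, rng).sum() == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            poisson_drive(-1.0, 0.1, 10, np.random.default_rng(0))

    def test_mean_count_matches_rate_dt_product(self):
        rng = np.random.default_rng(1)
        counts = poisson_drive(18_100.0, 0.1, 200_000, rng)
        se = np.sqrt(1.81 / counts.size)
        assert counts.mean() == pytest.approx(1.81, abs=5 * se)

    def test_free_membrane_mean_matches_rate_tau_j(self):
        # mu = nu_ext * tau_m * J_ext = 18.1 kHz * 10 ms * 0.1 mV = 18.1 mV
        mu = free_membrane_potential(duration=20.0, seed=11)
        assert mu == pytest.approx(18.1, abs=0.15)


class TestKernelEquivalence:
    """The numba block kernel and the NumPy reference step agree exactly."""

    def test_chunk_matches_repeated_reference_steps(self, neuron):
        cfg = NetworkConfig(n_e=6, n_i=3, gamma_ei=0.6, gamma_ie=0.6,
                            gamma_ii=0.4, r_ext=4000.0, dt=0.1, delay=0.5)
        w = build_static_wiring(cfg, seed=5)
        w.A[1, 0] = 2  # a multapse to exercise the dense E->E path
        w.A[2, 4] = 1
        n = cfg.n_total
        n_steps = 400
        rng = np.random.default_rng(42)
        randoms = rng.integers(0, 1 << LUT_BITS, size=(n_steps, n),
                               dtype=np.uint16)
        lut = poisson_count_lut(cfg.r_ext, cfg.dt)
        counts_per_step = lut[randoms].astype(np.int64)

        # reference path
        st = NetworkState.initial(cfg, neuron, seed=0)
        st.V[:] = np.linspace(0, 15, n)
        ref_counts = np.zeros(n, dtype=int)
        for s in range(n_steps):
            ref_counts[step(st, w, cfg, neuron, ext_counts=counts_per_step[s])] += 1

        # kernel path
        V = np.linspace(0, 15, n)
        refr = np.zeros(n, dtype=np.int64)
        C = np.zeros(cfg.n_e)
        pending = np.zeros((cfg.delay_steps + 1, n))
        counts = np.zeros(n, dtype=np.int64)
        bias = np.full(n, neuron.v_0)
        run_chunk(
            n_steps, V, refr, C, pending, 0,
            np.exp(-cfg.dt / neuron.tau_m), bias, neuron.v_reset, neuron.v_th,
            int(round(neuron.t_ref / cfg.dt)), True,
            cfg.j_ext, lut, 0, randoms, w.indptr, w.idx, w.w,
            w.A, cfg.j_e, cfg.n_e, 1.0, 0.0, counts,
            np.empty(0), np.empty(0, dtype=np.int64), 0, False, 0.0, cfg.dt,
            np.empty(0), False,
        )
        assert np.array_equal(counts, ref_counts)
        assert np.allclose(V, st.V, atol=1e-9)
        assert np.array_equal(refr, st.refr)


class TestSingleNeuron:
    def test_perpendicular_field_leaves_rate_at_baseline(self):
        base = simulate_single_neuron(0.0, duration=30.0, seed=1)
        perp = simulate_single_neuron(1.2, theta=np.pi / 2, duration=30.0, seed=1)
        assert perp == base  # cos(pi/2) nulls the bias; same seed, same drive

    def test_cosine_projection_equates_matched_conditions(self):
        a = simulate_single_neuron(0.1, theta=0.0, duration=30.0, seed=2)
        b = simulate_single_neuron(0.2, theta=np.pi / 3, duration=30.0, seed=2)
        assert a == b  # 0.2 * cos(pi/3) = 0.1 exactly, same drive stream

    def test_rate_monotone_in_effective_polarization(self):
        rates = [
            simulate_single_neuron(dv, duration=40.0, seed=3)
            for dv in (-0.8, -0.4, 0.0, 0.4, 0.8)
        ]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_identical_seed_reproduces_spike_count(self):
        r1 = simulate_single_neuron(0.05, duration=10.0, seed=9)
        r2 = simulate_single_neuron(0.05, duration=10.0, seed=9)
        assert r1 == r2
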