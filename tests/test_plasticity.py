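"""Unit and property tests of the homeostatic structural-plasticity rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdcsnet import (
    CalciumTrace,
    ElementPools,
    PlasticityParams,
    delete_elements,
    pair_free_elements,
    structural_update,
    update_calcium,
    update_elements,
)
from tdcsnet.plasticity import DemandReport

from conftest import make_pools_from_matrix


def make_trace(C, params):
    return CalciumTrace(
        C=np.asarray(C, dtype=float),
        beta_ca=params.beta_ca,
        tau_ca=params.tau_ca,
    )


class TestCalcium:
    def test_decay_over_one_time_constant(self):
        p = PlasticityParams()
        tr = make_trace([0.008], p)
        update_calcium(tr, np.zeros(1), dt=10.0)
        assert tr.C[0] == pytest.approx(0.008 * np.exp(-1.0), rel=1e-12)

    def test_spike_increments_by_beta_ca(self):
        p = PlasticityParams()
        tr = make_trace([0.0], p)
        update_calcium(tr, np.array([1]), dt=1e-9)
        assert tr.C[0] == pytest.approx(1e-4, rel=1e-9)

    def test_steady_firing_at_target_rate_averages_to_set_point(self):
        # a neuron firing at exactly 8 Hz has mean calcium
        # rate * beta_ca * tau_ca = 0.008, the set-point eps
        p = PlasticityParams()
        tr = make_trace([0.0], p)
        dt = 0.0125  # 10 steps per interspike interval at 8 Hz
        samples = []
        for k in range(40_000):
            spikes = np.array([1]) if k % 10 == 9 else np.zeros(1)
            update_calcium(tr, spikes, dt)
            samples.append(tr.C[0])
        mean_tail = np.mean(samples[len(samples) // 2:])
        assert mean_tail == pytest.approx(p.eps, rel=0.02)

    @given(
        c0=st.floats(0.0, 0.05),
        counts=st.lists(st.integers(0, 3), min_size=1, max_size=50),
        dt=st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_for_piecewise_constant_input(self, c0, counts, dt):
        """Iterated updates equal the closed-form solution of the calcium ODE."""
        p = PlasticityParams()
        tr = make_trace([c0], p)
        for s in counts:
            update_calcium(tr, np.array([s]), dt)
        n = len(counts)
        t_end = n * dt
        expected = c0 * np.exp(-t_end / p.tau_ca) + p.beta_ca * sum(
            s * np.exp(-(t_end - (k + 1) * dt) / p.tau_ca)
            for k, s in enumerate(counts)
        )
        assert tr.C[0] == pytest.approx(expected, rel=1e-9, abs=1e-15)


class TestElementGrowth:
    def test_set_point_is_a_fixed_point(self):
        p = PlasticityParams()
        pools = ElementPools.zeros(1)
        pools.z_pre[0] = pools.z_post[0] = 2.5
        pools.free_pre[0] = pools.free_post[0] = 2
        update_elements(pools, make_trace([p.eps], p), p, dt_struct=1.0)
        assert pools.z_pre[0] == 2.5 and pools.z_post[0] == 2.5

    @pytest.mark.parametrize("c_over_eps,sign", [(0.0, 1.0), (2.0, -1.0)])
    def test_growth_is_linear_and_symmetric_about_set_point(self, c_over_eps, sign):
        p = PlasticityParams(nu=0.004)  # growth rate in elements/s
        pools = ElementPools.zeros(1)
        pools.z_pre[0] = pools.z_post[0] = 5.0
        pools.free_pre[0] = pools.free_post[0] = 5
        update_elements(pools, make_trace([c_over_eps * p.eps], p), p, dt_struct=1.0)
        assert pools.z_pre[0] - 5.0 == pytest.approx(sign * 0.004, rel=1e-12)

    def test_integer_crossings_are_credited_to_free_pool(self):
        p = PlasticityParams(nu=1.0)
        pools = ElementPools.zeros(1)
        pools.z_pre[0] = pools.z_post[0] = 0.9
        rep = update_elements(pools, make_trace([0.0], p), p, dt_struct=0.2)
        assert rep.gained_pre[0] == 1
        assert pools.free_pre[0] == 1

    def test_z_clamps_at_zero(self):
        p = PlasticityParams(nu=1.0)
        pools = ElementPools.zeros(1)
        pools.z_pre[0] = pools.z_post[0] = 0.3
        update_elements(pools, make_trace([100 * p.eps], p), p, dt_struct=1.0)
        assert pools.z_pre[0] == 0.0


class TestPairing:
    def test_no_free_elements_no_change(self):
        A = np.zeros((3, 3), dtype=np.int32)
        pools = make_pools_from_matrix(A)
        assert pair_free_elements(pools, A, np.random.default_rng(0)) == 0
        assert A.sum() == 0

    def test_forced_pairing_forms_exactly_one_synapse(self):
        A = np.zeros((3, 3), dtype=np.int32)
        pools = make_pools_from_matrix(A, free_pre=[1, 0, 0], free_post=[0, 1, 0])
        n = pair_free_elements(pools, A, np.random.default_rng(0))
        assert n == 1
        assert A[1, 0] == 1  # synapse 1 <- 0
        assert pools.bound_pre[0] == 1 and pools.bound_post[1] == 1
        assert pools.free_pre.sum() == 0 and pools.free_post.sum() == 0

    def test_hub_bouton_holder_reaches_every_spine_holder(self):
        # 10 boutons on neuron 0, one spine on each of neurons 1..10:
        # every spine is matched, each holder receives exactly one contact
        n = 11
        A = np.zeros((n, n), dtype=np.int32)
        free_post = np.array([0] + [1] * 10)
        pools = make_pools_from_matrix(A, free_pre=[10] + [0] * 10,
                                       free_post=free_post)
        formed = pair_free_elements(pools, A, np.random.default_rng(3))
        assert formed == 10
        assert np.array_equal(A[1:, 0], np.ones(10, dtype=np.int32))

    def test_self_pairing_is_skipped_and_elements_stay_free(self):
        A = np.zeros((2, 2), dtype=np.int32)
        pools = make_pools_from_matrix(A, free_pre=[1, 0], free_post=[1, 0])
        formed = pair_free_elements(pools, A, np.random.default_rng(0))
        assert formed == 0
        assert pools.free_pre[0] == 1 and pools.free_post[0] == 1


class TestDeletion:
    def _report(self, n, deficit_pre=None, deficit_post=None):
        z = np.zeros(n, dtype=np.int64)
        return DemandReport(
            gained_pre=z.copy(), gained_post=z.copy(),
            deficit_pre=np.array(deficit_pre) if deficit_pre is not None else z.copy(),
            deficit_post=np.array(deficit_post) if deficit_post is not None else z.copy(),
        )

    def test_free_elements_are_consumed_before_synapses_break(self):
        A = np.zeros((2, 2), dtype=np.int32)
        A[1, 0] = 3
        pools = make_pools_from_matrix(A, free_pre=[1, 0])
        pools.z_pre[0] -= 1.0  # one bouton must go
        delete_elements(pools, self._report(2, deficit_pre=[1, 0]), A,
                        np.random.default_rng(0))
        assert A[1, 0] == 3  # no synapse broken
        assert pools.free_pre[0] == 0

    def test_forced_breakage_returns_counterpart_to_partner(self):
        A = np.zeros((2, 2), dtype=np.int32)
        A[1, 0] = 3  # neuron 0 has 3 bound boutons onto neuron 1
        pools = make_pools_from_matrix(A)
        pools.z_pre[0] -= 1.0
        delete_elements(pools, self._report(2, deficit_pre=[1, 0]), A,
                        np.random.default_rng(0))
        assert A[1, 0] == 2
        assert pools.bound_pre[0] == 2
        assert pools.free_post[1] == 1  # partner's spine freed
        pools.check(A)

    def test_excess_deficit_clamps_and_does_not_go_negative(self):
        A = np.zeros((2, 2), dtype=np.int32)
        A[1, 0] = 1
        pools = make_pools_from_matrix(A)
        pools.z_pre[0] = 0.0
        delete_elements(pools, self._report(2, deficit_pre=[5, 0]), A,
                        np.random.default_rng(0))
        assert A.sum() == 0
        assert pools.bound_pre[0] == 0 and pools.z_pre[0] == 0.0

    def test_sustained_high_calcium_dismantles_connectivity_monotonically(self):
        p = PlasticityParams(nu=2.0)
        n = 6
        rng = np.random.default_rng(5)
        A = rng.integers(0, 3, size=(n, n)).astype(np.int32)
        np.fill_diagonal(A, 0)
        pools = make_pools_from_matrix(A)
        trace = make_trace(np.full(n, 2 * p.eps), p)
        totals = [A.sum()]
        for _ in range(30):
            structural_update(pools, trace, A, p, 1.0, rng)
            trace.C[:] = 2 * p.eps  # hold the drive above the set-point
            totals.append(A.sum())
            pools.check(A)
        assert all(b <= a for a, b in zip(totals, totals[1:]))
        assert totals[-1] == 0


class TestConservation:
    """Every synapse binds exactly one bouton and one spine, always."""

    @given(seed=st.integers(0, 1_000))
    @settings(max_examples=25, deadline=None)
    def test_invariants_hold_through_random_update_sequences(self, seed):
        rng = np.random.default_rng(seed)
        p = PlasticityParams(nu=3.0)
        n = int(rng.integers(2, 20))
        A = np.zeros((n, n), dtype=np.int32)
        pools = ElementPools.zeros(n)
        trace = make_trace(np.zeros(n), p)
        for _ in range(40):
            # random calcium wander around the set-point drives both growth
            # and deletion phases
            trace.C[:] = rng.uniform(0, 3 * p.eps, size=n)
            structural_update(pools, trace, A, p, rng.uniform(0.05, 1.5), rng)
            pools.check(A)
            assert (A >= 0).all()
            assert np.diag(A).sum() == 0  # no autapses ever
            assert pools.bound_pre.sum() == A.sum()
            assert pools.bound_post.sum() == A.sum()
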