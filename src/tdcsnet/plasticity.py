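"""Calcium-based homeostatic structural plasticity of E->E connectivity.

Each excitatory neuron carries a calcium trace C(t) that increments by
``beta_ca`` per spike and decays with time constant ``tau_ca`` — a low-pass
proxy of its firing rate.  Presynaptic elements (boutons) and postsynaptic
elements (spines) both grow at rate ``nu * (1 - C/eps)``: below the set-point
``eps`` a neuron offers new elements, above it elements are removed.  Free
elements across the population are randomly combined into functional synapses
(one bouton + one spine, no self-pairing, multapses allowed); when an element
bound in a synapse must be removed, the synapse breaks and the partner's
counterpart element returns to its free pool.

Element counters ``z`` are continuous; the integer number of usable elements
is ``floor(z)``.  After every structural update the bookkeeping invariant

    floor(z_pre)  == free_pre  + bound_pre   (per neuron)
    floor(z_post) == free_post + bound_post  (per neuron)

holds, and ``sum(bound_pre) == sum(bound_post) == A.sum()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import ConfigurationError, PlasticityParams

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumTrace",
    "ElementPools",
    "DemandReport",
    "update_calcium",
    "update_elements",
    "pair_free_elements",
    "delete_elements",
    "structural_update",
]


@dataclass
class CalciumTrace:
    """Per-neuron calcium concentration with its update constants."""

    C: np.ndarray          # float64[n_e], dimensionless
    beta_ca: float = 1e-4  # increment per spike
    tau_ca: float = 10.0   # decay time constant, s

    @classmethod
    def zeros(cls, n: int, params: PlasticityParams) -> "CalciumTrace":
        return cls(
            C=np.zeros(n, dtype=np.float64),
            beta_ca=params.beta_ca,
            tau_ca=params.tau_ca,
        )


def update_calcium(trace: CalciumTrace, spikes: np.ndarray, dt: float) -> CalciumTrace:
    """Advance the calcium trace by ``dt`` seconds with per-neuron spike counts.

    Exact closed form for spikes registered at the end of the interval:
    ``C <- C * exp(-dt/tau_ca) + beta_ca * count``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    trace.C = trace.C * np.exp(-dt / trace.tau_ca) + trace.beta_ca * np.asarray(spikes)
    return trace


@dataclass
class ElementPools:
    """Continuous element counters and integer free/bound pools per neuron."""

    z_pre: np.ndarray       # float64[n_e]
    z_post: np.ndarray      # float64[n_e]
    free_pre: np.ndarray    # int64[n_e] unbound boutons
    free_post: np.ndarray   # int64[n_e] unbound spines
    bound_pre: np.ndarray   # int64[n_e] boutons engaged in synapses
    bound_post: np.ndarray  # int64[n_e] spines engaged in synapses

    @classmethod
    def zeros(cls, n: int) -> "ElementPools":
        z = lambda: np.zeros(n, dtype=np.float64)
        i = lambda: np.zeros(n, dtype=np.int64)
        return cls(z(), z(), i(), i(), i(), i())

    def check(self, A: np.ndarray | None = None) -> None:
        """Assert the bookkeeping invariants (used by tests and debug runs)."""
        for z, free, bound, kind in (
            (self.z_pre, self.free_pre, self.bound_pre, "pre"),
            (self.z_post, self.free_post, self.bound_post, "post"),
        ):
            if (free < 0).any() or (bound < 0).any():
                raise AssertionError(f"negative {kind} pool")
            if not np.array_equal(np.floor(z).astype(np.int64), free + bound):
                raise AssertionError(f"floor(z_{kind}) != free + bound")
        if A is not None:
            if not np.array_equal(A.sum(axis=0), self.bound_pre):
                raise AssertionError("column sums of A != bound_pre")
            if not np.array_equal(A.sum(axis=1), self.bound_post):
                raise AssertionError("row sums of A != bound_post")


@dataclass
class DemandReport:
    """Outcome of one element-growth update: newly available and deficient elements."""

    gained_pre: np.ndarray    # int64[n_e] new free boutons already credited
    gained_post: np.ndarray   # int64[n_e] new free spines already credited
    deficit_pre: np.ndarray   # int64[n_e] boutons that must be removed
    deficit_post: np.ndarray  # int64[n_e] spines that must be removed


def update_elements(
    pools: ElementPools,
    trace: CalciumTrace,
    params: PlasticityParams,
    dt_struct: float,
) -> DemandReport:
    """Grow or shrink the continuous element counters by one structural step.

    ``dz = nu * (1 - C/eps) * dt_struct`` for both element kinds, with ``z``
    clamped at zero.  Newly completed integer elements are credited to the
    free pools immediately; integer deficits are reported for
    :func:`delete_elements` to resolve.
    """
    if dt_struct <= 0:
        raise ConfigurationError("dt_struct must be positive")
    dz = params.nu * (1.0 - trace.C / params.eps) * dt_struct
    gained = []
    deficit = []
    for z, free, bound in (
        (pools.z_pre, pools.free_pre, pools.bound_pre),
        (pools.z_post, pools.free_post, pools.bound_post),
    ):
        z += dz
        np.maximum(z, 0.0, out=z)
        target = np.floor(z).astype(np.int64)
        have = free + bound
        g = np.maximum(target - have, 0)
        d = np.maximum(have - target, 0)
        free += g  # new elements are immediately available
        gained.append(g)
        deficit.append(d)
    return DemandReport(gained[0], gained[1], deficit[0], deficit[1])


def delete_elements(
    pools: ElementPools,
    report: DemandReport,
    A: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Resolve element deficits: consume free elements first, then break synapses.

    Bound elements to remove are drawn uniformly among the neuron's bound
    elements of that kind, so a multapse loses contacts in proportion to its
    multiplicity.  The partner of a broken synapse gets its counterpart
    element back as a free element.  Returns the per-neuron counts of freed
    counterpart elements.
    """
    n = A.shape[0]
    freed_pre = np.zeros(n, dtype=np.int64)
    freed_post = np.zeros(n, dtype=np.int64)

    for i in np.nonzero(report.deficit_pre)[0]:
        need = int(report.deficit_pre[i])
        take = min(int(pools.free_pre[i]), need)
        pools.free_pre[i] -= take
        need -= take
        if need == 0:
            continue
        col = A[:, i]
        bound_avail = int(col.sum())
        if need > bound_avail:
            logger.warning(
                "neuron %d: bouton deficit %d exceeds free+bound; clamping "
                "(runaway parameterization?)", i, report.deficit_pre[i]
            )
            need = bound_avail
            pools.z_pre[i] = 0.0
        if need == 0:
            continue
        partners = np.repeat(np.arange(n), col)
        chosen = rng.choice(partners.shape[0], size=need, replace=False)
        for p in partners[chosen]:
            A[p, i] -= 1
            pools.bound_pre[i] -= 1
            pools.bound_post[p] -= 1
            pools.free_post[p] += 1
            freed_post[p] += 1

    for i in np.nonzero(report.deficit_post)[0]:
        need = int(report.deficit_post[i])
        take = min(int(pools.free_post[i]), need)
        pools.free_post[i] -= take
        need -= take
        if need == 0:
            continue
        row = A[i, :]
        bound_avail = int(row.sum())
        if need > bound_avail:
            logger.warning(
                "neuron %d: spine deficit %d exceeds free+bound; clamping "
                "(runaway parameterization?)", i, report.deficit_post[i]
            )
            need = bound_avail
            pools.z_post[i] = 0.0
        if need == 0:
            continue
        partners = np.repeat(np.arange(n), row)
        chosen = rng.choice(partners.shape[0], size=need, replace=False)
        for p in partners[chosen]:
            A[i, p] -= 1
            pools.bound_post[i] -= 1
            pools.bound_pre[p] -= 1
            pools.free_pre[p] += 1
            freed_pre[p] += 1

    # keep floor(z) consistent with the remaining elements after breakage
    np.minimum(pools.z_pre, pools.free_pre + pools.bound_pre + 1.0 - 1e-12,
               out=pools.z_pre)
    np.minimum(pools.z_post, pools.free_post + pools.bound_post + 1.0 - 1e-12,
               out=pools.z_post)
    return {"freed_pre": freed_pre, "freed_post": freed_post}


def pair_free_elements(
    pools: ElementPools,
    A: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Randomly combine free boutons with free spines into new synapses.

    One shuffled pass: all free boutons and all free spines are listed with
    multiplicity, shuffled independently, and paired index-wise up to
    ``min(total_free_pre, total_free_post)``.  Pairs that would form an
    autapse are skipped (those elements stay free).  Returns the number of
    synapses formed.
    """
    total_pre = int(pools.free_pre.sum())
    total_post = int(pools.free_post.sum())
    if total_pre == 0 or total_post == 0:
        return 0
    boutons = np.repeat(np.arange(A.shape[0]), pools.free_pre)
    spines = np.repeat(np.arange(A.shape[0]), pools.free_post)
    rng.shuffle(boutons)
    rng.shuffle(spines)
    k = min(total_pre, total_post)
    pre = boutons[:k]
    post = spines[:k]
    ok = pre != post
    pre, post = pre[ok], post[ok]
    if pre.size == 0:
        return 0
    np.add.at(A, (post, pre), 1)
    np.add.at(pools.free_pre, pre, -1)
    np.add.at(pools.free_post, post, -1)
    np.add.at(pools.bound_pre, pre, 1)
    np.add.at(pools.bound_post, post, 1)
    return int(pre.size)


def structural_update(
    pools: ElementPools,
    trace: CalciumTrace,
    A: np.ndarray,
    params: PlasticityParams,
    dt_struct: float,
    rng: np.random.Generator,
) -> int:
    """One full structural-plasticity update: grow/shrink, delete, then pair.

    Returns the number of synapses formed in this update.
    """
    report = update_elements(pools, trace, params, dt_struct)
    delete_elements(pools, report, A, rng)
    return pair_free_elements(pools, A, rng)
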