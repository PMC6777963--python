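"""Readouts: windowed firing rates, group connectivity, exponential integrals.

The connectivity of a population of n neurons with synapse-count matrix
A[post, pre] is Gamma = (1/n^2) * sum(A).  For the accumulated outcome of a
stimulation episode the relaxation-phase connectivity change is fitted with a
sum of three exponential decays,

    Gamma(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + A3 exp(-t/tau3),

and summarized by its time integral I_G = sum_k A_k tau_k, which extrapolates
transients that outlive the simulated relaxation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .params import ConfigurationError
from .protocols import GroupAssignment

__all__ = [
    "ConnectivityTrace",
    "ExpFit",
    "FitError",
    "firing_rate",
    "group_connectivity",
    "fit_triple_exponential",
    "connectivity_integral",
]


class FitError(RuntimeError):
    """Raised when the exponential fit cannot produce a trustworthy result."""


@dataclass
class ConnectivityTrace:
    """Time series of mean connectivity for one (source, target) group pair."""

    times: np.ndarray   # s
    gamma: np.ndarray   # synapses per ordered neuron pair

    def restricted(self, t0: float) -> "ConnectivityTrace":
        m = self.times >= t0
        return ConnectivityTrace(self.times[m], self.gamma[m])


def firing_rate(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    window: tuple[float, float],
    members: np.ndarray,
    n_total: int | None = None,
) -> float:
    """Arithmetic-mean firing rate (spikes/s) of ``members`` in a time window.

    ``spike_times`` in the same unit as ``window`` bounds (seconds).  Each
    neuron's rate is its spike count divided by the window length; the group
    rate is the mean over group members, including silent ones.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ConfigurationError("empty group: firing rate undefined")
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError("window must have positive length")
    n_total = n_total or (int(max(spike_ids.max(initial=-1), members.max())) + 1)
    sel = (spike_times >= t0) & (spike_times < t1)
    counts = np.bincount(np.asarray(spike_ids)[sel].astype(np.int64),
                         minlength=n_total)
    return float(counts[members].mean() / (t1 - t0))


def group_connectivity(
    A: np.ndarray, assignment: GroupAssignment
) -> dict[tuple[int, int], float]:
    """Mean connectivity for every ordered (source-group, target-group) pair.

    Off-diagonal blocks are averaged over |target| * |source| ordered pairs;
    within-group blocks divide by |g|^2, consistent with the whole-network
    n^-2 convention (the zero diagonal is part of the average).
    """
    out: dict[tuple[int, int], float] = {}
    idx = [assignment.members(g) for g in range(assignment.n_groups)]
    for s, src in enumerate(idx):
        for t, tgt in enumerate(idx):
            if src.size == 0 or tgt.size == 0:
                out[(s, t)] = float("nan")
                continue
            block = A[np.ix_(tgt, src)]
            out[(s, t)] = float(block.sum() / (tgt.size * src.size))
    return out


def _model(t: np.ndarray, amps: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.exp(-t[:, None] / taus[None, :]) @ amps


def _linear_amplitudes(
    t: np.ndarray, y: np.ndarray, taus: np.ndarray
) -> tuple[np.ndarray, float]:
    X = np.exp(-t[:, None] / taus[None, :])
    amps, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = float(np.sqrt(np.mean((X @ amps - y) ** 2)))
    return amps, resid


@dataclass
class ExpFit:
    """Triple-exponential decomposition of a relaxation-phase trace."""

    amplitudes: np.ndarray  # (3,), connectivity units; signs are free
    taus: np.ndarray        # (3,), s; positive, sorted ascending
    residual: float         # RMS misfit
    ok: bool = True
    message: str = ""

    @property
    def integral(self) -> float:
        """I_G = sum_k A_k tau_k (connectivity * s)."""
        return float(np.dot(self.amplitudes, self.taus))


def fit_triple_exponential(
    trace: ConnectivityTrace,
    t0: float = 0.0,
    tau_bounds: tuple[float, float] = (0.5, 1.0e4),
    n_ladder: int = 9,
) -> ExpFit:
    """Nonlinear least-squares fit of three exponential decays to a trace.

    The trace is restricted to ``t >= t0`` and time-shifted so the fit starts
    at zero (I_G is invariant to that shift only through the refit, so the
    shift convention is: integration starts at the relaxation onset).
    Initialization ladder: all tau triples from a log-spaced grid over
    ``tau_bounds`` with amplitudes from a linear solve; the best candidate is
    refined with bounded least squares over (amplitudes, log taus).
    Amplitude signs are free; taus are constrained positive and returned
    sorted.  Degenerate (non-decaying, flat) traces are flagged rather than
    extrapolated.
    """
    sub = trace.restricted(t0)
    if sub.times.size < 30:
        raise ConfigurationError("need at least 30 samples beyond t0 to fit")
    t = sub.times - sub.times[0]
    y = sub.gamma.astype(np.float64)

    scale = float(np.max(np.abs(y))) if np.max(np.abs(y)) > 0 else 1.0
    if float(np.std(y)) <= 1e-10 * scale:
        return ExpFit(
            amplitudes=np.zeros(3), taus=np.full(3, np.inf),
            residual=float(np.std(y)), ok=False,
            message="flat trace: no decay to fit (infinite-tau limit)",
        )

    lo, hi = tau_bounds
    grid = np.geomspace(lo, hi, n_ladder)
    from itertools import combinations

    candidates = []
    for combo in combinations(range(n_ladder), 3):
        taus = grid[list(combo)]
        amps, resid = _linear_amplitudes(t, y, taus)
        candidates.append((resid, amps, taus))
    candidates.sort(key=lambda c: c[0])

    def residuals(x: np.ndarray) -> np.ndarray:
        return _model(t, x[:3], np.exp(x[3:])) - y

    bounds = (
        np.concatenate([np.full(3, -np.inf), np.full(3, np.log(lo))]),
        np.concatenate([np.full(3, np.inf), np.full(3, np.log(hi))]),
    )
    best_sol = None
    for resid0, amps0, taus0 in candidates[:12]:
        x0 = np.concatenate([amps0, np.log(taus0)])
        try:
            sol = least_squares(residuals, x0, bounds=bounds, max_nfev=600,
                                x_scale="jac")
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best_sol is None or sol.cost < best_sol.cost:
            best_sol = sol
    if best_sol is None:
        amps0, taus0 = candidates[0][1], candidates[0][2]
        return ExpFit(amps0, taus0, candidates[0][0], ok=False,
                      message="all refinement attempts failed")
    amps = best_sol.x[:3]
    taus = np.exp(best_sol.x[3:])
    order = np.argsort(taus)
    resid = float(np.sqrt(np.mean(best_sol.fun**2)))
    return ExpFit(amplitudes=amps[order], taus=taus[order], residual=resid,
                  ok=True, message="")


def connectivity_integral(fit: ExpFit) -> float:
    """Time integral I_G = sum_k A_k tau_k of a valid exponential fit."""
    if not fit.ok:
        raise FitError(f"cannot integrate a flagged fit: {fit.message}")
    return fit.integral
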