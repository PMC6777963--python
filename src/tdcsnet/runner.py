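"""Reproducible experiment orchestration.

A run is a pure function of its :class:`RunConfig`: growth from an unconnected
E-E graph to the homeostatic equilibrium, then the stimulation protocol, then
relaxation, with group connectivity sampled on a regular grid and firing rates
in disjoint windows.  Per-trial seeds derive deterministically from the master
seed.  The grown state can be checkpointed and shared across protocol variants
of a sweep: stimulation only starts after the growth period, so for a fixed
trial seed the grown network is identical whatever the protocol.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import measurements as meas
from ._kernel import run_chunk
from .network import LUT_BITS, Wiring, build_static_wiring, poisson_count_lut
from .params import (
    ConfigurationError,
    NetworkConfig,
    NeuronParams,
    PlasticityParams,
    to_dict,
)
from .plasticity import CalciumTrace, ElementPools, structural_update
from .protocols import GroupAssignment, ProtocolSchedule, assign_groups

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TrialResult",
    "ExperimentResult",
    "RunawayDynamicsError",
    "grow_network",
    "run_experiment",
    "sweep",
    "desk_network",
    "paper_network",
]


class RunawayDynamicsError(RuntimeError):
    """Population rate exceeded the ceiling for a sustained period."""


def paper_network() -> NetworkConfig:
    """Full-scale network configuration (10,000 E / 2,500 I, 10% wiring)."""
    return NetworkConfig()


def desk_network(n_e: int = 1000) -> NetworkConfig:
    """Down-scaled network that preserves the full-scale synaptic in-degrees.

    Scaling down the neuron count at fixed connection probability would scale
    down the recurrent in-degrees with it and move the network out of the
    inhibition-dominated operating point.  The desk preset therefore keeps
    the expected in-degrees of the full-scale model (1,000 E->I, 250 I->E,
    250 I->I) by raising the connection probabilities on the smaller
    population; with 1,000 E and 250 I neurons the static blocks become
    all-to-all.  Weights, drive and plasticity parameters are unchanged; the
    homeostatic set-point rate is size-free.
    """
    n_i = max(1, n_e // 4)
    full = NetworkConfig()
    k_ei = full.gamma_ei * full.n_e   # E inputs per I neuron
    k_ie = full.gamma_ie * full.n_i   # I inputs per E neuron
    k_ii = full.gamma_ii * full.n_i
    return replace(
        full,
        n_e=n_e,
        n_i=n_i,
        gamma_ei=min(1.0, k_ei / n_e),
        gamma_ie=min(1.0, k_ie / n_i),
        gamma_ii=min(1.0, k_ii / n_i),
    )


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one experiment."""

    schedule: ProtocolSchedule
    network: NetworkConfig = field(default_factory=NetworkConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    n_trials: int = 1
    seed: int = 0
    sample_dt: float = 1.0        # connectivity sampling cadence, s
    rate_window: float = 5.0      # firing-rate window, s
    rate_ceiling: float = 200.0   # spikes/s; sustained excess aborts the run
    baseline_fraction: float = 0.1  # tail share of growth used as baseline
    record_spikes: bool = False

    def describe(self) -> dict:
        return {
            "schedule": to_dict(self.schedule),
            "network": to_dict(self.network),
            "neuron": to_dict(self.neuron),
            "plasticity": to_dict(self.plasticity),
            "n_trials": self.n_trials,
            "seed": self.seed,
            "sample_dt": self.sample_dt,
            "rate_window": self.rate_window,
        }


@dataclass
class Checkpoint:
    """Full state at a phase boundary; continuation reproduces a fresh run."""

    t: float
    chunk_index: int
    V: np.ndarray
    refr: np.ndarray
    pending: np.ndarray
    slot: int
    trace: CalciumTrace
    pools: ElementPools
    wiring: Wiring
    assignment: GroupAssignment
    struct_rng_state: dict
    drive_rng_state: dict

    def clone(self) -> "Checkpoint":
        return copy.deepcopy(self)


@dataclass
class TrialResult:
    trial: int
    assignment: GroupAssignment
    times: np.ndarray                 # connectivity sample times, s
    conn: dict                        # (src_group, tgt_group) -> gamma array
    gamma_ee: np.ndarray              # whole excitatory population
    rate_times: np.ndarray            # window end times, s
    rates: dict                       # group -> rate array (spikes/s)
    rate_e: np.ndarray                # population-mean excitatory rate
    baseline: dict                    # (g, h) -> pre-stimulation mean gamma
    fit: meas.ExpFit | None = None    # within-G1 relaxation fit
    i_g: float | None = None
    spikes: tuple | None = None       # (ids, times_s) if recorded

    def conn_trace(self, src: int, tgt: int) -> meas.ConnectivityTrace:
        return meas.ConnectivityTrace(self.times, self.conn[(src, tgt)])


@dataclass
class ExperimentResult:
    config: RunConfig
    trials: list
    summary: dict


class _Engine:
    """Simulation engine for one trial."""

    def __init__(self, config: RunConfig, trial: int):
        self.config = config
        self.trial = trial
        ss = np.random.SeedSequence([config.seed, trial])
        wiring_seed, assign_seed, struct_seed, drive_seed = ss.generate_state(4)
        net, neu, pl = config.network, config.neuron, config.plasticity

        self.wiring = build_static_wiring(net, int(wiring_seed))
        self.assignment = assign_groups(
            net.n_e, config.schedule.fractions, int(assign_seed)
        )
        self.struct_rng = np.random.default_rng(int(struct_seed))
        self.drive_rng = np.random.default_rng(int(drive_seed))
        self.pools = ElementPools.zeros(net.n_e)
        self.trace = CalciumTrace.zeros(net.n_e, pl)

        self.V = np.full(net.n_total, neu.v_0, dtype=np.float64)
        self.refr = np.zeros(net.n_total, dtype=np.int64)
        self.pending = np.zeros(
            (net.delay_steps + 1, net.n_total), dtype=np.float64
        )
        self.slot = 0
        self.t = 0.0
        self.chunk_index = 0

        self.chunk_steps = int(round(pl.dt_struct * 1000.0 / net.dt))
        if self.chunk_steps < 1:
            raise ConfigurationError("dt_struct must cover at least one dt")
        self.decay = float(np.exp(-net.dt / neu.tau_m))
        self.ca_decay = float(np.exp(-net.dt * 1e-3 / pl.tau_ca))
        self.ref_steps = int(round(neu.t_ref / net.dt))
        self.pois_lut = poisson_count_lut(net.r_ext, net.dt)

        # measurement accumulators
        self.sample_every = max(1, int(round(config.sample_dt / pl.dt_struct)))
        self.window_chunks = max(1, int(round(config.rate_window / pl.dt_struct)))
        self._window_counts = np.zeros(net.n_total, dtype=np.int64)
        self._window_fill = 0
        self.samp_times: list[float] = []
        self.samp_conn: list[dict] = []
        self.samp_gamma: list[float] = []
        self.rate_times: list[float] = []
        self.rate_groups: list[np.ndarray] = []
        self.rate_e: list[float] = []
        self._runaway_windows = 0
        self._group_idx = [
            self.assignment.members(g) for g in range(self.assignment.n_groups)
        ]
        self.spike_chunks: list[tuple[np.ndarray, np.ndarray]] = []
        cap = int(net.n_total * pl.dt_struct * 400) + 64
        self._rec_t = np.empty(cap if config.record_spikes else 0)
        self._rec_id = np.empty(cap if config.record_spikes else 0, dtype=np.int64)

    # -- state round-trips ---------------------------------------------------

    def checkpoint(self) -> Checkpoint:
        return Checkpoint(
            t=self.t, chunk_index=self.chunk_index,
            V=self.V.copy(), refr=self.refr.copy(),
            pending=self.pending.copy(), slot=self.slot,
            trace=copy.deepcopy(self.trace), pools=copy.deepcopy(self.pools),
            wiring=copy.deepcopy(self.wiring),
            assignment=self.assignment,
            struct_rng_state=self.struct_rng.bit_generator.state,
            drive_rng_state=self.drive_rng.bit_generator.state,
        )

    def restore(self, ck: Checkpoint) -> None:
        ck = ck.clone()
        self.t, self.chunk_index = ck.t, ck.chunk_index
        self.V, self.refr = ck.V, ck.refr
        self.pending, self.slot = ck.pending, ck.slot
        self.trace, self.pools, self.wiring = ck.trace, ck.pools, ck.wiring
        self.struct_rng = np.random.default_rng()
        self.struct_rng.bit_generator.state = ck.struct_rng_state
        self.drive_rng = np.random.default_rng()
        self.drive_rng.bit_generator.state = ck.drive_rng_state

    # -- simulation ----------------------------------------------------------

    def _bias_vector(self, group_dv: tuple[float, ...]) -> np.ndarray:
        net, neu = self.config.network, self.config.neuron
        bias = np.full(net.n_total, neu.v_0, dtype=np.float64)
        for g, v in enumerate(group_dv):
            if v != 0.0:
                bias[self._group_idx[g]] += v
        return bias

    def run_phase(self, duration: float, group_dv: tuple[float, ...]) -> None:
        """Advance by ``duration`` seconds under constant group polarization."""
        cfg = self.config
        net, neu, pl = cfg.network, cfg.neuron, cfg.plasticity
        n_chunks = int(round(duration / pl.dt_struct))
        bias = self._bias_vector(group_dv)
        counts = np.zeros(net.n_total, dtype=np.int64)
        rec = cfg.record_spikes
        for _ in range(n_chunks):
            counts[:] = 0
            randoms = self.drive_rng.integers(
                0, 1 << LUT_BITS, size=(self.chunk_steps, net.n_total),
                dtype=np.uint16,
            )
            self.slot, nrec = run_chunk(
                self.chunk_steps, self.V, self.refr, self.trace.C,
                self.pending, self.slot,
                self.decay, bias, neu.v_reset, neu.v_th, self.ref_steps, True,
                net.j_ext, self.pois_lut, 0, randoms,
                self.wiring.indptr, self.wiring.idx, self.wiring.w,
                self.wiring.A, net.j_e, net.n_e,
                self.ca_decay, pl.beta_ca,
                counts,
                self._rec_t, self._rec_id, 0, rec, self.t * 1000.0, net.dt,
                np.empty(0), False,
            )
            if rec and nrec:
                self.spike_chunks.append(
                    (self._rec_id[:nrec].copy(), self._rec_t[:nrec] / 1000.0)
                )
            self.t += pl.dt_struct
            self.chunk_index += 1
            structural_update(
                self.pools, self.trace, self.wiring.A, pl, pl.dt_struct,
                self.struct_rng,
            )
            self._collect(counts)

    def _collect(self, counts: np.ndarray) -> None:
        cfg = self.config
        n_e = cfg.network.n_e
        if self.chunk_index % self.sample_every == 0:
            self.samp_times.append(self.t)
            self.samp_conn.append(
                meas.group_connectivity(self.wiring.A, self.assignment)
            )
            self.samp_gamma.append(float(self.wiring.A.sum()) / n_e**2)
        self._window_counts += counts
        self._window_fill += 1
        if self._window_fill >= self.window_chunks:
            w = self._window_fill * cfg.plasticity.dt_struct
            self.rate_times.append(self.t)
            per_neuron = self._window_counts / w
            self.rate_groups.append(
                np.array([per_neuron[m].mean() for m in self._group_idx])
            )
            e_rate = float(per_neuron[:n_e].mean())
            self.rate_e.append(e_rate)
            self._window_counts[:] = 0
            self._window_fill = 0
            if e_rate > cfg.rate_ceiling:
                self._runaway_windows += 1
                if self._runaway_windows >= 3:
                    raise RunawayDynamicsError(
                        f"excitatory population rate {e_rate:.1f} spikes/s "
                        f"exceeded the ceiling {cfg.rate_ceiling} spikes/s for "
                        f"3 consecutive windows at t = {self.t:.1f} s: the "
                        "network is in a pathological high-rate state"
                    )
            else:
                self._runaway_windows = 0

    # -- results -------------------------------------------------------------

    def result(self) -> TrialResult:
        cfg = self.config
        sched = cfg.schedule
        times = np.array(self.samp_times)
        conn = {
            key: np.array([s[key] for s in self.samp_conn])
            for key in (self.samp_conn[0] if self.samp_conn else {})
        }
        rates_arr = (
            np.vstack(self.rate_groups)
            if self.rate_groups
            else np.empty((0, self.assignment.n_groups))
        )
        baseline = {}
        grow_mask = times <= sched.t_grow
        n_base = max(1, int(round(cfg.baseline_fraction * grow_mask.sum())))
        for key, g in conn.items():
            pre = g[grow_mask]
            baseline[key] = float(pre[-n_base:].mean()) if pre.size else float("nan")

        fit = None
        i_g = None
        t0 = sched.relaxation_start
        relax_mask = times >= t0
        if relax_mask.sum() >= 30:
            delta = conn[(0, 0)][relax_mask] - baseline[(0, 0)]
            try:
                fit = meas.fit_triple_exponential(
                    meas.ConnectivityTrace(times[relax_mask], delta)
                )
                if fit.ok:
                    i_g = fit.integral
            except ConfigurationError:
                fit = None

        spikes = None
        if cfg.record_spikes and self.spike_chunks:
            ids = np.concatenate([c[0] for c in self.spike_chunks])
            ts = np.concatenate([c[1] for c in self.spike_chunks])
            spikes = (ids, ts)

        return TrialResult(
            trial=self.trial,
            assignment=self.assignment,
            times=times,
            conn=conn,
            gamma_ee=np.array(self.samp_gamma),
            rate_times=np.array(self.rate_times),
            rates={g: rates_arr[:, g] for g in range(self.assignment.n_groups)},
            rate_e=np.array(self.rate_e),
            baseline=baseline,
            fit=fit,
            i_g=i_g,
            spikes=spikes,
        )


def grow_network(config: RunConfig, trial: int = 0) -> tuple[_Engine, Checkpoint]:
    """Run the growth period of one trial and checkpoint the grown state."""
    engine = _Engine(config, trial)
    zeros = tuple(0.0 for _ in config.schedule.delta_v)
    engine.run_phase(config.schedule.t_grow, zeros)
    return engine, engine.checkpoint()


def _run_trial(config: RunConfig, trial: int, engine: _Engine | None = None) -> TrialResult:
    if engine is None:
        engine = _Engine(config, trial)
        phases = list(config.schedule.phases())
    else:
        phases = [p for p in config.schedule.phases() if p.label != "grow"]
    for phase in phases:
        if phase.duration > 0:
            engine.run_phase(phase.duration, phase.delta_v)
    return engine.result()


def run_experiment(config: RunConfig, output_dir: str | Path | None = None) -> ExperimentResult:
    """Execute growth -> stimulation -> relaxation for all trials.

    Identical configs produce identical result bundles.  If ``output_dir`` is
    given, connectivity traces, rate traces and a JSON summary (plus spike
    records when enabled) are written there as plain-text files.
    """
    trials = [_run_trial(config, k) for k in range(config.n_trials)]
    result = ExperimentResult(
        config=config, trials=trials, summary=_summarize(config, trials)
    )
    if output_dir is not None:
        _write_bundle(result, Path(output_dir))
    return result


def _summarize(config: RunConfig, trials: list) -> dict:
    sched = config.schedule
    final_within = [float(t.conn[(0, 0)][-1]) for t in trials]
    baseline_within = [t.baseline[(0, 0)] for t in trials]
    i_gs = [t.i_g for t in trials if t.i_g is not None]
    return {
        "n_trials": len(trials),
        "final_within_g1_mean": float(np.mean(final_within)),
        "final_within_g1_sd": float(np.std(final_within, ddof=1))
        if len(trials) > 1 else 0.0,
        "baseline_within_g1_mean": float(np.mean(baseline_within)),
        "final_rate_e_mean": float(np.mean([t.rate_e[-1] for t in trials])),
        "i_g_mean": float(np.mean(i_gs)) if i_gs else None,
        "i_g_sd": float(np.std(i_gs, ddof=1)) if len(i_gs) > 1 else None,
        "total_stim_time": sched.total_stim_time,
    }


def _write_bundle(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in result.trials:
        for (s, g), gam in t.conn.items():
            rows.extend(
                {"trial": t.trial, "time_s": ti, "src_group": s + 1,
                 "tgt_group": g + 1, "gamma": gi}
                for ti, gi in zip(t.times, gam)
            )
    pd.DataFrame(rows).to_csv(out / "connectivity.csv", index=False)
    rrows = []
    for t in result.trials:
        for g, r in t.rates.items():
            rrows.extend(
                {"trial": t.trial, "time_s": ti, "group": g + 1, "rate_hz": ri}
                for ti, ri in zip(t.rate_times, r)
            )
    pd.DataFrame(rrows).to_csv(out / "rates.csv", index=False)
    for t in result.trials:
        if t.spikes is not None:
            ids, ts = t.spikes
            order = np.argsort(ts, kind="stable")
            pd.DataFrame({"neuron": ids[order], "time_ms": ts[order] * 1000.0}
                         ).to_csv(out / f"spikes_trial{t.trial}.tsv",
                                  sep="\t", index=False)
    payload = {"config": result.config.describe(), "summary": result.summary}
    (out / "summary.json").write_text(json.dumps(payload, indent=2))


def sweep(
    base: RunConfig,
    schedules: list[tuple[str, ProtocolSchedule]],
    reuse_growth: bool = True,
    tail_window: int = 25,
) -> pd.DataFrame:
    """Run a family of protocols and tabulate I_G and final connectivity.

    All schedules must share the growth duration; when ``reuse_growth`` is
    set, each trial's network is grown once and the grown checkpoint is
    restored for every protocol variant (exact, since stimulation starts only
    after growth).  ``tail_window`` is the number of trailing connectivity
    samples averaged into the ``tail_*`` columns.  Per-point failures are
    recorded and the sweep continues.
    """
    t_grows = {s.t_grow for _, s in schedules}
    if reuse_growth and len(t_grows) != 1:
        raise ConfigurationError("cannot reuse growth across differing t_grow")
    rows = []
    for trial in range(base.n_trials):
        grown: Checkpoint | None = None
        if reuse_growth:
            cfg0 = replace(base, schedule=schedules[0][1])
            engine, grown = grow_network(cfg0, trial)
        for label, sched in schedules:
            cfg = replace(base, schedule=sched)
            row = {"label": label, "trial": trial,
                   "delta_v1": sched.delta_v[0], "f_g1": sched.fractions[0],
                   "mode": sched.mode, "t_on": sched.t_on, "t_off": sched.t_off,
                   "n_cycles": sched.n_cycles}
            try:
                if reuse_growth:
                    engine = _Engine(cfg, trial)
                    engine.restore(grown)
                    # growth samples are not re-recorded on restore; recover
                    # the baseline from the grown matrix itself
                    res = _run_trial(cfg, trial, engine=engine)
                    base_conn = meas.group_connectivity(
                        grown.wiring.A, engine.assignment
                    )
                    res.baseline = {k: float(v) for k, v in base_conn.items()}
                    res = _refit(res, cfg)
                else:
                    res = _run_trial(cfg, trial)
                n_groups = res.assignment.n_groups
                if n_groups > 1:
                    cross = 0.5 * (res.conn[(0, 1)] + res.conn[(1, 0)])
                    tail_cross = float(cross[-tail_window:].mean())
                    baseline_cross = 0.5 * (res.baseline[(0, 1)]
                                            + res.baseline[(1, 0)])
                else:
                    tail_cross = float("nan")
                    baseline_cross = float("nan")
                row.update(
                    i_g=res.i_g,
                    final_within=float(res.conn[(0, 0)][-1]),
                    tail_within=float(res.conn[(0, 0)][-tail_window:].mean()),
                    tail_cross=tail_cross,
                    baseline_cross=baseline_cross,
                    baseline_within=res.baseline[(0, 0)],
                    final_rate_e=float(res.rate_e[-1]) if res.rate_e.size else None,
                    error="",
                )
            except RunawayDynamicsError as exc:
                logger.warning("sweep point %s failed: %s", label, exc)
                row.update(i_g=None, final_within=None, tail_within=None,
                           tail_cross=None, baseline_cross=None,
                           baseline_within=None, final_rate_e=None,
                           error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def _refit(res: TrialResult, cfg: RunConfig) -> TrialResult:
    """Recompute the relaxation fit after a baseline adjustment."""
    sched = cfg.schedule
    t0 = sched.relaxation_start
    mask = res.times >= t0
    if mask.sum() >= 30:
        delta = res.conn[(0, 0)][mask] - res.baseline[(0, 0)]
        try:
            fit = meas.fit_triple_exponential(
                meas.ConnectivityTrace(res.times[mask], delta)
            )
            res.fit = fit
            res.i_g = fit.integral if fit.ok else None
        except ConfigurationError:
            res.fit, res.i_g = None, None
    return res
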