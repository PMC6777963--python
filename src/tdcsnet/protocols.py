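"""Stimulation protocols: group montages and piecewise-constant polarization.

A tDCS montage is abstracted as a partition of the excitatory population into
up to three groups, each receiving a constant membrane polarization
``delta_v`` while stimulation is on.  Inhibitory neurons are never polarized:
only excitatory cells, with their extended and anisotropic morphology, are
assumed sensitive to the field.  Stimulation begins only after the structural
growth period; repetitive protocols cycle between an on-phase of length
``t_on`` and either a pause (on-off) or an opposite-polarity phase
(alternating) of length ``t_off``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .params import ConfigurationError

__all__ = [
    "GroupAssignment",
    "ProtocolSchedule",
    "Phase",
    "assign_groups",
    "delta_v_at",
    "table4_preset",
    "preset_names",
    "Preset",
]


@dataclass
class GroupAssignment:
    """Disjoint partition of the excitatory population into stimulation groups."""

    fractions: tuple[float, ...]
    membership: np.ndarray  # int64[n_e], group index per excitatory neuron

    @property
    def n_groups(self) -> int:
        return len(self.fractions)

    def members(self, g: int) -> np.ndarray:
        return np.nonzero(self.membership == g)[0]

    def sizes(self) -> tuple[int, ...]:
        return tuple(int((self.membership == g).sum()) for g in range(self.n_groups))


def assign_groups(
    n_e: int, fractions: tuple[float, ...], seed: int
) -> GroupAssignment:
    """Uniformly random disjoint partition with largest-remainder rounding.

    ``fractions`` must sum to one; group sizes are deterministic given
    ``n_e`` and ``fractions``, membership is a seeded random permutation.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions):
        raise ConfigurationError("group fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("group fractions must sum to 1")
    quotas = [f * n_e for f in fractions]
    sizes = [math.floor(q) for q in quotas]
    remainder = n_e - sum(sizes)
    by_frac = sorted(range(len(quotas)), key=lambda g: quotas[g] - sizes[g],
                     reverse=True)
    for g in by_frac[:remainder]:
        sizes[g] += 1
    membership = np.repeat(np.arange(len(sizes), dtype=np.int64), sizes)
    rng = np.random.default_rng(seed)
    rng.shuffle(membership)
    return GroupAssignment(fractions=fractions, membership=membership)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Per-group polarization as a piecewise-constant function of time.

    ``mode`` is one of ``uni``, ``bi``, ``tri`` (single stimulation episode of
    length ``t_on`` followed by ``t_off`` of relaxation), ``on_off`` or
    ``alternating`` (``n_cycles`` repetitions of ``t_on`` + ``t_off``, with
    the off-phase at zero or opposite polarity respectively, followed by
    ``t_post`` of relaxation).  All durations in seconds, polarizations in mV.
    """

    mode: str
    fractions: tuple[float, ...]
    delta_v: tuple[float, ...]       # on-phase polarization per group, mV
    t_grow: float = 750.0
    t_on: float = 150.0              # t_stim, or t1 for repetitive runs
    t_off: float = 300.0             # t_relax, or t2 for repetitive runs
    n_cycles: int = 1
    t_post: float = 0.0              # extra relaxation after the last cycle

    def __post_init__(self) -> None:
        if self.mode not in ("uni", "bi", "tri", "on_off", "alternating"):
            raise ConfigurationError(f"unknown protocol mode {self.mode!r}")
        if len(self.fractions) != len(self.delta_v):
            raise ConfigurationError("fractions and delta_v lengths differ")
        if min(self.t_grow, self.t_on) < 0 or self.t_off < 0 or self.t_post < 0:
            raise ConfigurationError("durations must be non-negative")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")

    @property
    def total_stim_time(self) -> float:
        return self.n_cycles * self.t_on

    @property
    def t_end(self) -> float:
        return (
            self.t_grow
            + self.n_cycles * (self.t_on + self.t_off)
            + self.t_post
        )

    def phases(self) -> Iterator["Phase"]:
        """Piecewise-constant phases covering [0, t_end)."""
        zeros = tuple(0.0 for _ in self.delta_v)
        t = 0.0
        yield Phase(t, self.t_grow, zeros, "grow")
        t += self.t_grow
        for c in range(self.n_cycles):
            yield Phase(t, self.t_on, self.delta_v, "stim")
            t += self.t_on
            if self.mode == "alternating":
                off = tuple(-v for v in self.delta_v)
                label = "stim_opposite"
            else:
                off = zeros
                label = "relax"
            yield Phase(t, self.t_off, off, label)
            t += self.t_off
        if self.t_post > 0:
            yield Phase(t, self.t_post, zeros, "relax")

    @property
    def relaxation_start(self) -> float:
        """Time at which the final stimulation phase ends."""
        if self.mode == "alternating":
            return self.t_grow + self.n_cycles * (self.t_on + self.t_off)
        return self.t_grow + (self.n_cycles - 1) * (self.t_on + self.t_off) + self.t_on


@dataclass(frozen=True)
class Phase:
    t_start: float
    duration: float
    delta_v: tuple[float, ...]  # per group, mV
    label: str

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


def delta_v_at(
    t: float, schedule: ProtocolSchedule, assignment: GroupAssignment
) -> np.ndarray:
    """Per-excitatory-neuron polarization (mV) at simulated time ``t`` (s)."""
    if t < 0:
        raise ConfigurationError("t must be non-negative")
    group_dv = tuple(0.0 for _ in schedule.delta_v)
    for phase in schedule.phases():
        if phase.t_start <= t < phase.t_end:
            group_dv = phase.delta_v
            break
    dv = np.zeros(assignment.membership.shape[0], dtype=np.float64)
    for g, v in enumerate(group_dv):
        if v != 0.0:
            dv[assignment.membership == g] = v
    return dv


# ---------------------------------------------------------------------------
# Catalogue of stimulation configurations used in the original experiments
# ---------------------------------------------------------------------------

FIG4_INTENSITIES = (-1.2, -0.8, -0.4, 0.4, 0.8, 1.2)
FIG5_DUTY_CYCLES = ((75, 75), (75, 150), (150, 75), (150, 150), (150, 300),
                    (300, 150))
FIG5_INTENSITIES = (0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class Preset:
    """A catalogued stimulation configuration, possibly with parameter grids.

    ``base`` holds the schedule shared by all runs of the preset; ``grid``
    maps parameter names (``f_g1``, ``delta_v1``, ``duty``) to the lists that
    were systematically varied.  :meth:`expand` yields one concrete schedule
    per grid point.
    """

    name: str
    base: ProtocolSchedule
    grid: dict = field(default_factory=dict)

    def expand(self) -> list[tuple[str, ProtocolSchedule]]:
        runs = [(self.name, self.base)]
        if "duty" in self.grid:
            runs = [
                (
                    f"{self.name}[t1={t1},t2={t2}]",
                    replace(
                        self.base,
                        t_on=float(t1),
                        t_off=float(t2),
                        n_cycles=int(round(6000.0 / t1)),
                    ),
                )
                for (t1, t2) in self.grid["duty"]
            ]
        if "f_g1" in self.grid:
            new = []
            for label, sched in runs:
                for f1 in self.grid["f_g1"]:
                    fr = _refit_fractions(sched.fractions, f1)
                    new.append((f"{label}[f={f1}]", replace(sched, fractions=fr)))
            runs = new
        if "delta_v1" in self.grid:
            new = []
            for label, sched in runs:
                for v1 in self.grid["delta_v1"]:
                    dv = _refit_delta_v(sched, v1)
                    new.append((f"{label}[dv={v1}]", replace(sched, delta_v=dv)))
            runs = new
        return runs


def _refit_fractions(fractions: tuple[float, ...], f1: float) -> tuple[float, ...]:
    if len(fractions) == 2:
        return (f1, 1.0 - f1)
    # tri-group: G2 mirrors G1, remainder unstimulated
    return (f1, f1, 1.0 - 2 * f1)


def _refit_delta_v(sched: ProtocolSchedule, v1: float) -> tuple[float, ...]:
    old = sched.delta_v
    if len(old) == 1:
        return (v1,)
    # preserve the sign relation of the remaining groups to group 1
    out = [v1]
    for v in old[1:]:
        if v == 0.0:
            out.append(0.0)
        else:
            out.append(math.copysign(v1, v) if abs(v) == abs(old[0]) else v)
    return tuple(out)


def _catalogue() -> dict[str, Preset]:
    cat: dict[str, Preset] = {}

    def add(name: str, base: ProtocolSchedule, **grid) -> None:
        cat[name] = Preset(name=name, base=base, grid=dict(grid))

    add("fig2_depolarizing",
        ProtocolSchedule("uni", (0.1, 0.9), (0.1, 0.0), 750.0, 150.0, 300.0))
    add("fig2_hyperpolarizing",
        ProtocolSchedule("uni", (0.1, 0.9), (-0.1, 0.0), 750.0, 150.0, 300.0))
    add("fig3_tri_group",
        ProtocolSchedule("tri", (0.3, 0.3, 0.4), (0.1, -0.1, 0.0),
                         750.0, 150.0, 300.0))
    add("fig3_bi_group",
        ProtocolSchedule("bi", (0.3, 0.7), (0.1, -0.1), 750.0, 150.0, 300.0))
    add("fig4_bi_group",
        ProtocolSchedule("bi", (0.1, 0.9), (0.4, -0.4), 750.0, 150.0, 5850.0),
        f_g1=(0.1, 0.3, 0.5, 0.7), delta_v1=FIG4_INTENSITIES)
    add("fig4_uni_group",
        ProtocolSchedule("uni", (0.1, 0.9), (0.4, 0.0), 750.0, 150.0, 5850.0),
        f_g1=(0.1, 0.3, 0.5, 0.7), delta_v1=FIG4_INTENSITIES)
    add("fig4_tri_group",
        ProtocolSchedule("tri", (0.1, 0.1, 0.8), (0.4, -0.4, 0.0),
                         750.0, 150.0, 5850.0),
        f_g1=(0.1, 0.2, 0.3, 0.4), delta_v1=FIG4_INTENSITIES)
    add("fig4_half_half",
        ProtocolSchedule("bi", (0.5, 0.5), (0.4, -0.4), 750.0, 150.0, 5850.0),
        delta_v1=FIG4_INTENSITIES)
    add("fig5_duty_grid",
        ProtocolSchedule("on_off", (0.1, 0.9), (0.1, 0.0), 750.0, 150.0, 150.0,
                         n_cycles=40),
        duty=FIG5_DUTY_CYCLES)
    add("fig5_asymmetric",
        ProtocolSchedule("on_off", (0.1, 0.9), (0.1, 0.0), 750.0, 75.0, 150.0,
                         n_cycles=80),
        delta_v1=FIG5_INTENSITIES)
    add("fig6_on_off",
        ProtocolSchedule("on_off", (0.1, 0.9), (0.1, 0.0), 750.0, 150.0, 150.0,
                         n_cycles=3))
    add("fig6_alternating_half",
        ProtocolSchedule("alternating", (0.1, 0.9), (0.05, 0.0), 750.0, 150.0,
                         150.0, n_cycles=3))
    add("fig6_alternating",
        ProtocolSchedule("alternating", (0.1, 0.9), (0.1, 0.0), 750.0, 150.0,
                         150.0, n_cycles=3))
    # convenience alias used when asking for the intensity grid alone
    cat["fig4_intensity_grid"] = cat["fig4_uni_group"]
    return cat


_CATALOGUE = _catalogue()


def preset_names() -> list[str]:
    return sorted(_CATALOGUE)


def table4_preset(name: str) -> Preset:
    """Look up a catalogued stimulation configuration by name."""
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
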