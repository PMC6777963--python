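"""Parameter containers for the neuron, network, and plasticity models.

Units follow the conventions of the underlying model: membrane quantities in
mV and ms, calcium and structural-plasticity time constants in seconds,
population rates in spikes/s.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron parameters.

    The membrane potential decays toward the resting value ``v_0`` (possibly
    shifted by a polarization bias), jumps on synaptic events, and on crossing
    ``v_th`` the neuron spikes, is reset to ``v_reset`` and held there for the
    refractory period ``t_ref``.
    """

    tau_m: float = 10.0   # membrane time constant, ms
    t_ref: float = 2.0    # absolute refractory period, ms
    v_0: float = 0.0      # resting potential, mV
    v_reset: float = 10.0  # post-spike reset potential, mV
    v_th: float = 20.0    # firing threshold, mV

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ConfigurationError("tau_m must be positive")
        if self.t_ref < 0:
            raise ConfigurationError("t_ref must be non-negative")
        if not (self.v_0 <= self.v_reset < self.v_th):
            raise ConfigurationError("require v_0 <= v_reset < v_th")


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, static wiring probabilities, synaptic weights and drive.

    The excitatory-to-excitatory block is not described here because it is
    grown by the structural-plasticity rule; only connections involving
    inhibitory neurons are static Bernoulli wiring.
    """

    n_e: int = 10_000          # excitatory neurons
    n_i: int = 2_500           # inhibitory neurons
    gamma_ei: float = 0.1      # E -> I connection probability
    gamma_ie: float = 0.1      # I -> E connection probability
    gamma_ii: float = 0.1      # I -> I connection probability
    j_e: float = 0.1           # excitatory PSP amplitude, mV
    j_i: float = -0.8          # inhibitory PSP amplitude, mV
    r_ext: float = 30_000.0    # external Poisson rate per neuron, spikes/s
    j_ext: float = 0.1         # external synapse amplitude, mV (taken equal to j_e)
    delay: float = 1.0         # synaptic transmission delay, ms
    dt: float = 0.1            # integration step, ms

    def __post_init__(self) -> None:
        if self.n_e <= 0 or self.n_i < 0:
            raise ConfigurationError("population sizes must be positive")
        for name in ("gamma_ei", "gamma_ie", "gamma_ii"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.j_e <= 0:
            raise ConfigurationError("j_e must be positive")
        if self.j_i >= 0:
            raise ConfigurationError("j_i must be negative")
        if self.r_ext < 0:
            raise ConfigurationError("r_ext must be non-negative")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.delay <= 0:
            raise ConfigurationError("delay must be positive")
        k = self.delay / self.dt
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ConfigurationError("delay must be a positive integer multiple of dt")

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.dt))


@dataclass(frozen=True)
class PlasticityParams:
    """Calcium-based homeostatic structural-plasticity parameters.

    The calcium trace of each excitatory neuron increments by ``beta_ca`` per
    spike and decays with ``tau_ca``; at a firing rate r its stationary mean is
    ``r * beta_ca * tau_ca``, so the set-point ``eps`` corresponds to a target
    rate ``eps / (beta_ca * tau_ca)`` (8 Hz with the defaults).  Synaptic
    elements grow at rate ``nu * (1 - C/eps)``.

    ``nu`` is expressed here in elements per second.  The growth-rate constant
    of this model family is conventionally quoted as 0.004 in per-millisecond
    units (the native time unit of the simulators it originated in), which is
    4.0 elements/s; this is the only value consistent with networks that
    reach their structural equilibrium within a 750-s growth period and lose
    of order 10^2 synapses per neuron during a 150-s suprathreshold episode.
    """

    eps: float = 0.008       # calcium set-point, dimensionless
    nu: float = 4.0          # element growth rate at C = 0, elements/s
    tau_ca: float = 10.0     # calcium decay time constant, s
    beta_ca: float = 1e-4    # calcium increment per spike
    dt_struct: float = 0.1   # structural update cadence, s

    def __post_init__(self) -> None:
        if min(self.eps, self.tau_ca, self.beta_ca, self.dt_struct) <= 0:
            raise ConfigurationError("eps, tau_ca, beta_ca, dt_struct must be positive")
        if self.nu < 0:
            raise ConfigurationError("nu must be non-negative")

    @property
    def target_rate(self) -> float:
        """Firing rate (spikes/s) at which the calcium trace sits at eps."""
        return self.eps / (self.beta_ca * self.tau_ca)


def to_dict(obj) -> dict:
    """Serialize any of the parameter dataclasses to a plain dict."""
    return asdict(obj)
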