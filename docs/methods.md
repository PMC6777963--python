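# Methods

## Model

### Neurons and network

All neurons are current-based leaky integrate-and-fire point neurons,

    tau_m dV_i/dt = -(V_i - V_0) + tau_m * sum_j J_ij S_j(t - d) + dV_i(t),

with tau_m = 10 ms, resting potential V_0 = 0 mV, threshold V_th = 20 mV,
reset V_reset = 10 mV and absolute refractory period t_ref = 2 ms.  Synapses
are delta pulses: a presynaptic spike deflects the target potential by J_E =
0.1 mV (excitatory) or J_I = -0.8 mV (inhibitory) after a transmission delay
d.  dV_i(t) is the polarization imposed by the stimulation field; it is
implemented as a shift of the steady-state potential, equivalent to a
constant somatic current of amplitude dV/R.  In the single-neuron
experiments the effective polarization is dV * cos(theta), where theta is
the angle between the field vector and the somato-dendritic axis; network
protocols assign effective polarizations to groups directly.  Only
excitatory neurons are polarized — inhibitory interneurons, being compact
and isotropic, are taken to be insensitive to the field.

The full-scale network has 10,000 excitatory and 2,500 inhibitory neurons.
Connections involving inhibitory neurons are static and random (10%
connection probability, no self-connections); every neuron receives
independent 30-kHz Poisson drive through 0.1-mV synapses.  The E-E graph
starts empty and is grown by the plasticity rule; multiple synapses per
ordered pair (multapses) are allowed.

### Homeostatic structural plasticity

Each excitatory neuron carries a calcium trace C(t), a low-pass proxy of its
firing rate:

    dC/dt = -C / tau_Ca + beta_Ca * S(t),    tau_Ca = 10 s, beta_Ca = 1e-4.

At stationary rate r the trace averages to r * beta_Ca * tau_Ca, so the
set-point eps = 0.008 corresponds to a target rate of 8 spikes/s.  Both
presynaptic elements (boutons) and postsynaptic elements (spines) obey the
linear growth rule

    dz/dt = nu * (1 - C / eps),

growing while the neuron fires below target and shrinking above it.  Element
counters are continuous with floor(z) usable elements; newly completed
elements enter a free pool, and at every structural update all free boutons
and spines in the population are shuffled and paired index-wise into
synapses (no self-pairing; skipped elements stay free).  When an element
bound in a synapse must be removed, the synapse is chosen uniformly among
the neuron's bound elements of that kind — a multapse therefore loses
contacts in proportion to its multiplicity — and the partner's counterpart
element returns to the partner's free pool.  Free elements are consumed
before bound ones; free elements never decay.

**Growth-rate constant.**  The growth rate is conventionally quoted as
nu = 0.004 in the per-millisecond units native to the simulators this model
family originated in.  We use nu = 4.0 elements/s (the same quantity in SI
units).  This is the only reading consistent with the model's published
dynamics: growth from an empty E-E graph to structural equilibrium within a
750-s growth period, and losses of order 10^2 synapses per neuron during a
150-s suprathreshold episode.  At 0.004 elements/s a neuron could grow at
most three elements in the entire growth period and the network could never
reach its set-point.

### Stimulation protocols

A protocol is a partition of the excitatory population into up to three
groups (uni/bi/tri montages; sizes by largest-remainder rounding, membership
a seeded random permutation fixed for the whole run) plus a
piecewise-constant schedule: a growth period with no stimulation, then
``n_cycles`` repetitions of an on-phase (t1) followed by a pause (on-off) or
an opposite-polarity phase (alternating) of length t2, then a final
relaxation.  The catalogue in `tdcsnet.protocols` reproduces the published
configurations (figure-named presets), including the intensity and
duty-cycle grids.

### Measurements

Firing rates are spike counts in disjoint 5-s windows, averaged
arithmetically over group members.  Connectivity between groups g -> h is
the mean synapse count over ordered pairs; within-group blocks divide by
|g|^2, consistent with the n^-2 convention for the whole population.  The
accumulated outcome of a stimulation episode is the integral of the
relaxation-phase connectivity change: the within-assembly trace, minus its
pre-stimulation baseline (mean over the final 10% of the growth period), is
fitted with three exponential decays and summarized by I_G = sum_k A_k
tau_k.  Amplitude signs are free (overshoot produces mixed signs); decay
constants are constrained to [0.5, 1e4] s and returned sorted.  The fit uses
an initialization ladder — all tau triples from a 9-point log-spaced grid,
amplitudes from a linear solve — with bounded nonlinear least-squares
refinement of the best twelve candidates; three-exponential fits are
ill-conditioned and a single local refinement is not reliable.  Flat or
non-decaying traces are flagged rather than extrapolated, and a flagged fit
refuses to produce an integral.

## Numerical scheme

Time is discretized at dt = 0.1 ms (resolving t_ref exactly; configurable).
Between events the membrane potential is propagated by the exact exponential
solution toward its bias-shifted steady state; delayed recurrent PSPs and
external Poisson events are applied at the end of each step, and threshold
ties break toward spiking.  During refractoriness the potential is clamped
at V_reset and all input is discarded.  The synaptic delay defaults to
d = 1 ms (an integer number of steps; spikes in transit live in a ring
buffer of per-target accumulated currents, so delivery is exact).  External
Poisson counts are drawn per neuron and step by indexing a precomputed
inverse-CDF table with one raw 16-bit variate — class probabilities are
exact to one part in 2^16 (1.5e-5, far below any physically meaningful
scale), the table stays resident in L1 cache, and the lookup is what makes
microsecond-resolution simulation of long growth periods tractable on one
core.  All variates come from a single seeded PCG64 stream per trial, so
runs are bit-reproducible from (config, seed); the kernel is compiled with
strict IEEE floating-point semantics (no fast-math reassociation) so
realizations also reproduce across machines.  Calcium decays by
a precomputed per-step factor and increments at spike times — identical to
the closed-form solution of the calcium ODE for spikes registered at step
ends (verified to machine precision in the tests).  Structural updates run
every dt_struct = 100 ms; with tau_Ca = 10 s >> dt_struct the discretization
error of the growth rule is negligible.

The reference implementation of one integration step (`tdcsnet.network.step`,
plain NumPy) defines the semantics; the production path is a numba-compiled
block kernel verified against it step-for-step in the test suite.

## Down-scaling for desk runs

Full-scale runs (12,500 neurons, relaxation phases of thousands of seconds)
are not desk-reproducible.  Scaled runs keep all intensive parameters —
weights, drive, polarizations, group fractions, plasticity constants, hence
the 8-Hz set-point — and reduce neuron count and durations.  Reducing
neuron count at fixed connection probability would also scale down the
recurrent in-degrees and destroy the inhibition-dominated balance (at
N_E = 1000 and 10% wiring the inhibitory in-degree drops from 250 to 25 and
the static network fires far above the set-point, so the growth rule never
engages).  `desk_network` therefore preserves the full-scale expected
in-degrees (1,000 E->I, 250 I->E, 250 I->I) by raising connection
probabilities on the smaller population.  The grown scaled network then
reaches 7.9–8.0 spikes/s after the standard 750-s growth period — the same
homeostatic equilibrium as the full model, with correspondingly larger
per-pair connectivity (the equilibrium E-E in-degree of ~900 synapses per
neuron is size-free, so mean connectivity scales as 1/N_E).

The property experiments (assembly formation, intensity/focality/montage
trends, repetition effects) use 300-s growth periods at N_E = 300-500.
N_E = 300 is the smallest network that still sits below the set-point at
birth and equilibrates well inside the growth period (at N_E = 200 the
static network fires above 8 Hz and cannot grow); the assembly-formation and
repetition comparisons use N_E = 500, where the equilibrium in-degree
(~340 synapses per neuron) is larger relative to the elements turned over by
one stimulation episode and the post-stimulus rebound distortion is smaller.
Durations are shortened in proportion (e.g. 100-s duty cycles); stimulation
intensities, fractions and plasticity constants are never changed.

One finite-size effect matters for how assembly formation is read out: in a
small network each connectivity block carries a quenched random offset of
order 10^-2 synapses per pair simply from the finite number of pairs, while
the assembly effect itself is of the same order.  At full scale every block
starts at the same connectivity, so "within exceeds cross" and "within gains
more than cross" coincide; at desk scale only the baseline-referenced
comparison (each block's change relative to its own grown value) is
meaningful, and that is what the tests assert.  Scaled-down property runs
demonstrate orderings and mechanisms, not the paper-scale magnitudes.

## What the generated data do and do not emulate

All inputs are generated: Poisson background, random wiring, protocol
schedules.  The model abstracts the stimulated tissue as a homogeneous,
non-spatial network with uniform polarization within each group; it contains
no electrode geometry or field inhomogeneity, no conductance-based synapses,
no axonal or dendritic polarization, and no Hebbian or functional
plasticity.  Passing tests therefore show that the homeostatic
structural-plasticity mechanism produces the reported phenomena under these
idealized conditions — not that real cortical tissue does.

## Safety rails and degenerate inputs

Sustained population rates above a configurable ceiling (default
200 spikes/s for three consecutive windows) abort a run with a diagnostic:
this is the pathological high-rate regime in which very strong stimulation
puts the network, and silently continuing would only accumulate meaningless
deletions.  Sweeps record per-point failures and continue.  An element
deficit exceeding a neuron's free plus bound elements clamps z at zero and
logs a warning (a sign of runaway parameterization).  Empty measurement
groups and non-decaying fit traces raise instead of returning silent
defaults.
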