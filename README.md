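# tdcsnet

Spiking-network simulations of how weak transcranial direct-current
stimulation (tDCS) remodels cortical connectivity.  The package is for
computational neuroscientists who want to study the hypothesis that tDCS
aftereffects arise from *homeostatic structural plasticity*: a recurrent
network of excitatory (E) and inhibitory (I) leaky integrate-and-fire
neurons in which E-E synapses are continuously created and deleted so that
each neuron defends a target firing rate, perturbed by the sub-millivolt
membrane polarization a stimulation field imposes.

## Model in brief

Membrane dynamics (current-based LIF, delta synapses):

    tau_m dV_i/dt = -V_i + tau_m * sum_j J_ij S_j(t - d) + dV_i(t)

with tau_m = 10 ms, V_th = 20 mV, V_reset = 10 mV, t_ref = 2 ms, J_E =
0.1 mV, J_I = -0.8 mV, 30-kHz Poisson drive per neuron, and dV the
polarization of stimulated (excitatory) neurons — at most fractions of a
millivolt, far below threshold, yet enough to shift firing rates by >10%.

Each excitatory neuron tracks its activity through a calcium trace
(dC/dt = -C/tau_Ca + beta_Ca S(t)) and grows or removes synaptic elements
(axonal boutons, dendritic spines) at rate

    dz/dt = nu (1 - C / eps),

so firing below the set-point rate eps/(beta_Ca tau_Ca) = 8 Hz creates
elements and firing above it deletes them (breaking synapses frees the
partner's counterpart element).  Free boutons and spines pair randomly into
synapses.  Stimulation perturbs this equilibrium; the rebound rewires the
stimulated group into a *cell assembly* with elevated internal connectivity
that long outlives the stimulation itself.

Outcomes are quantified by group firing rates, group-resolved mean
connectivity Gamma(t), and the integral of the relaxation-phase connectivity
change, I_G = sum_k A_k tau_k, from a triple-exponential fit
Gamma(t) = sum_k A_k exp(-t/tau_k).

## Worked example

Growing a desk-scale network (300 E / 75 I, full-scale in-degrees preserved)
from an empty E-E graph to the homeostatic equilibrium:

    $ python examples/02_growth_to_set_point.py
    target rate eps/(beta_ca*tau_ca) = 8.0 spikes/s

       t [s]   rate [Hz]   Gamma_EE   mean C/eps
          30       7.43      0.156        0.869
          60       7.54      0.185        0.948
          90       7.77      0.199        0.972
         ...
         240       8.02      0.224        0.996
         300       7.97      0.226        0.996

The population rate climbs to the 8-Hz set-point as recurrent excitation
builds up, and element growth stops there (C/eps -> 1): this grown state is
the baseline for every stimulation experiment.  A stimulation episode then
remodels it:

    $ python examples/03_cell_assembly_formation.py
    trial 0: connectivity gain over baseline — within G1 +0.0065, G1<->rest +0.0019
    trial 1: connectivity gain over baseline — within G1 +0.0175, G1<->rest +0.0000

    mean over trials: within-group gain +0.0120 vs cross-group +0.0010

The stimulated 10% gain far more connectivity among themselves than with the
rest of the network — a cell assembly formed by a 0.1-mV polarization.
(Exact numbers vary with the seed; `examples/` contains one script per
capability.)

Library use mirrors the examples:

```python
from tdcsnet import ProtocolSchedule, RunConfig, desk_network, run_experiment

sched = ProtocolSchedule("uni", fractions=(0.1, 0.9), delta_v=(0.1, 0.0),
                         t_grow=300.0, t_on=150.0, t_off=300.0)
res = run_experiment(RunConfig(schedule=sched, network=desk_network(300),
                               n_trials=5, seed=42))
print(res.summary)
```

A thin CLI wraps the common chores: `tdcsnet list-presets` prints the
catalogued stimulation configurations (figure-named presets with their
intensity and duty-cycle grids), `tdcsnet run --preset fig2_depolarizing
--seed 1 --out out/` runs one end to end, and `tdcsnet fit trace.csv` fits a
stored connectivity trace.

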