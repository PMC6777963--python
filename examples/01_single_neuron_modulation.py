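"""Firing-rate modulation of a background-driven neuron by weak polarization.

A single LIF neuron receives 18.1-kHz Poisson background through 0.1-mV
synapses: its free membrane potential fluctuates around
nu * tau_m * J = 18.1 mV, just below the 20-mV threshold, so it fires at
roughly 8 spikes/s.  A somatic polarization of only +/-0.1 mV — the weakest
deflection reported to have physiological effects in tDCS experiments —
shifts the rate by more than 10%.  The effective bias scales with the cosine
of the angle between the field and the somato-dendritic axis.
"""

import numpy as np

from tdcsnet import free_membrane_potential, simulate_single_neuron

mu = free_membrane_potential(duration=100.0, seed=1)
print(f"free membrane potential: {mu:.2f} mV (analytic 18.1 mV)")

base = simulate_single_neuron(0.0, duration=100.0, seed=2)
print(f"baseline rate: {base:.2f} spikes/s")

print("\npolarization dependence (theta = 0):")
for dv in (-1.2, -0.4, -0.1, 0.1, 0.4, 1.2):
    r = simulate_single_neuron(dv, duration=100.0, seed=2)
    print(f"  dV = {dv:+5.2f} mV -> {r:6.2f} spikes/s ({(r - base) / base:+6.1%})")

print("\nfield-angle dependence (dV = 1.2 mV):")
for theta in (0.0, np.pi / 3, np.pi / 2):
    r = simulate_single_neuron(1.2, theta=theta, duration=100.0, seed=2)
    print(f"  theta = {theta:4.2f} rad -> {r:6.2f} spikes/s")
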