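"""Single-neuron integration and the power-law STDP rule.

Builds one current-based LIF neuron under constant bias current, compares
the simulated membrane trajectory against the closed-form solution, and
applies the STDP pair rule to a synapse for both spike orderings.
"""

import math

from embsnn import (KernelConfig, LIFCurrentParams, Network,
                    STDPPowerLawSynapse, stdp_update)

p = LIFCurrentParams(I_e=350.0)          # subthreshold: R*I_e = 14 mV
net = Network(KernelConfig(seed=1))
neuron = net.create("lif_current", 1, p)
net.simulate(20.0)

v_sim = net.get_voltages(neuron)[1][0]
R = p.tau_m / p.C_m
v_ref = p.E_L + R * p.I_e * (1 - math.exp(-20.0 / p.tau_m))
print(f"membrane after 20 ms: simulated {v_sim:.9f} mV, "
      f"closed form {v_ref:.9f} mV, |error| = {abs(v_sim - v_ref):.2e} mV")
# the exact propagator reproduces the analytic solution to ~1e-12 mV

syn = STDPPowerLawSynapse(weight=1.0, w0=1.0)
w_pot = stdp_update(syn, +10.0)          # pre 10 ms before post
w_dep = stdp_update(syn, -10.0)          # post 10 ms before pre
print(f"STDP from w=1: potentiation (dt=+10 ms) -> {w_pot:.6f}, "
      f"depression (dt=-10 ms) -> {w_dep:.6f}")
# potentiation adds lambda*w0^(1-mu)*w^mu*exp(-dt/tau+); depression is
# multiplicative, so repeated depression can never cross zero
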