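"""Single-neuron integration oracles.

The current-based neuron uses an exact exponential propagator, so it must
match the closed-form membrane solution at every grid point to 1e-9 mV and
a heavily oversampled reference integrator to 1e-6 mV.  The conductance
neuron's integrating-factor update is held to 1e-4 mV against the same
style of reference.
"""

import math

import numpy as np
import pytest

from embsnn import (KernelConfig, LIFConductanceParams, LIFCurrentParams,
                    Network, StaticSynapse)
from conftest import rk4_trajectory

H = 0.1


def _single_neuron(params, model="lif_current"):
    net = Network(KernelConfig(seed=1))
    pop = net.create(model, 1, params)
    return net, pop


def test_constant_current_matches_closed_form_everywhere():
    p = LIFCurrentParams(I_e=350.0)      # subthreshold: R*I = 14 mV < 15 mV
    net, pop = _single_neuron(p)
    R = p.tau_m / p.C_m
    for k in range(1, 301):
        net.simulate(H)
        v = net.get_voltages(pop)[1][0]
        v_ref = p.E_L + R * p.I_e * (1.0 - math.exp(-k * H / p.tau_m))
        assert abs(v - v_ref) < 1e-9


def test_suprathreshold_first_spike_time_is_ceil_of_closed_form():
    p = LIFCurrentParams(I_e=400.0)
    net, pop = _single_neuron(p)
    rec = net.create("spike_recorder", 1)
    net.connect(pop, rec)
    net.simulate(50.0)
    ev = net.get_spikes(rec)
    R = p.tau_m / p.C_m
    t_star = p.tau_m * math.log(R * p.I_e / (R * p.I_e - (p.V_th - p.E_L)))
    assert ev["t"][0] == pytest.approx(math.ceil(t_star / H) * H, abs=1e-12)


def test_zero_input_resting_fixed_point():
    # the exact propagator holds the rest state to float precision; the
    # conductance quadrature to its quadrature error
    for model, params, tol in [("lif_current", LIFCurrentParams(), 1e-12),
                               ("lif_conductance", LIFConductanceParams(), 1e-8)]:
        net, pop = _single_neuron(params, model)
        net.simulate(100.0)
        assert net.get_voltages(pop)[1][0] == pytest.approx(params.E_L, abs=tol)


def test_single_psc_event_matches_oversampled_reference():
    p = LIFCurrentParams()
    net, pop = _single_neuron(p)
    gen = net.create("spike_generator", 1, {"spike_times": [1.0]})
    w = 100.0
    net.connect(gen, pop, "one_to_one", StaticSynapse(weight=w, delay=1.0))
    V, psc = [], []
    for _ in range(300):
        net.simulate(H)
        V.append(net.get_voltages(pop)[1][0])
        psc.append(net.workers[0].blocks["lif_current"].y2[0])

    def f(t, y):
        y1, y2, v = y
        return np.array([-y1 / p.tau_syn, y1 - y2 / p.tau_syn,
                         -(v - p.E_L) / p.tau_m + y2 / p.C_m])

    # jump of w*e/tau_syn in y1 at the arrival time (2.0 ms), then RK4 at
    # 1000x oversampling
    grid = np.arange(0, 300 + 1) * H
    i_on = 20
    ref = np.full(300, p.E_L)
    ref[:i_on] = rk4_trajectory(f, [0, 0, p.E_L], grid[: i_on + 1], nsub=10)[:, 2]
    y0 = [w * math.e / p.tau_syn, 0.0, p.E_L]
    ref[i_on:] = rk4_trajectory(f, y0, grid[i_on:], nsub=1000)[:, 2]
    assert np.max(np.abs(np.array(V) - ref)) < 1e-6
    # the alpha PSC peaks at exactly the weight, tau_syn after arrival
    psc = np.array(psc)
    assert psc.max() == pytest.approx(w, abs=1e-9)
    assert grid[1 + int(psc.argmax())] == pytest.approx(2.0 + p.tau_syn, abs=1e-12)


def test_single_conductance_event_matches_oversampled_reference():
    p = LIFConductanceParams(V_th=1e9)
    net, pop = _single_neuron(p, "lif_conductance")
    gen = net.create("spike_generator", 1, {"spike_times": [1.0]})
    w, tau_a = 5.0, 2.0
    net.connect(gen, pop, "one_to_one",
                StaticSynapse(weight=w, delay=1.0, receptor="AMPA"))
    V = []
    for _ in range(300):
        net.simulate(H)
        V.append(net.get_voltages(pop)[1][0])

    def f(t, y):
        g1, g2, v = y
        return np.array([-g1 / tau_a, g1 - g2 / tau_a,
                         (-p.g_L * (v - p.E_L) - g2 * (v - 0.0)) / p.C_m])

    grid = np.arange(0, 300 + 1) * H
    i_on = 20
    ref = np.full(300, p.E_L)
    y0 = [w * math.e / tau_a, 0.0, p.E_L]
    ref[i_on:] = rk4_trajectory(f, y0, grid[i_on:], nsub=1000)[:, 2]
    assert np.max(np.abs(np.array(V) - ref)) < 1e-4


def test_conductance_decay_is_monotone_to_rest():
    p = LIFConductanceParams()
    net, pop = _single_neuron(p, "lif_conductance")
    net.workers[0].blocks["lif_conductance"].V[:] = -60.0
    V = []
    for _ in range(1000):
        net.simulate(H)
        V.append(net.get_voltages(pop)[1][0])
    assert (np.diff(V) <= 1e-9).all()
    assert V[-1] == pytest.approx(p.E_L, abs=1e-3)


def test_saturating_excitation_never_exceeds_reversal_potential():
    p = LIFConductanceParams(V_th=1e9)
    net, pop = _single_neuron(p, "lif_conductance")
    gen = net.create("poisson_generator", 1, {"rate": 50000.0})
    net.connect(gen, pop, syn=StaticSynapse(weight=300.0, delay=1.0,
                                            receptor="AMPA"))
    vmax = -np.inf
    for _ in range(200):
        net.simulate(1.0)
        vmax = max(vmax, net.get_voltages(pop)[1][0])
    e_exc = max(r.E_rev for r in p.receptors)
    assert vmax <= e_exc + 1e-9


def test_refractory_clamps_to_reset():
    p = LIFCurrentParams(I_e=1000.0, t_ref=2.0)
    net, pop = _single_neuron(p)
    rec = net.create("spike_recorder", 1)
    net.connect(pop, rec)
    net.simulate(100.0)
    ev = net.get_spikes(rec)
    # inter-spike intervals can never beat the refractory period
    assert np.diff(ev["t"]).min() > p.t_ref - 1e-9
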