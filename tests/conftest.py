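"""Shared fixtures and hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_mixed_network(n_workers: int, seed: int = 11):
    """A small network exercising every model kind and rule family:
    current- and conductance-based neurons, a parrot relay, Poisson drive,
    plastic and static synapses, and Gaussian wiring on a sheet."""
    from embsnn import (KernelConfig, LIFConductanceParams, LIFCurrentParams,
                        Network, STDPPowerLawSynapse, StaticSynapse)
    from embsnn.netbuilders import place_neurons_2d

    net = Network(KernelConfig(seed=seed, n_workers=n_workers))
    exc = net.create("lif_current", 30, LIFCurrentParams(), name="exc")
    pos = place_neurons_2d(20, 1.0, seed, stream_key=31)
    cond = net.create("lif_conductance", 20, LIFConductanceParams(),
                      positions=pos, name="cond")
    par = net.create("parrot", 5, name="relay")
    drive = net.create("poisson_generator", 1, {"rate": 12000.0}, name="drive")
    rec = net.create("spike_recorder", 1, name="rec")

    net.connect(drive, exc, syn=StaticSynapse(weight=60.0, delay=1.0))
    net.connect(exc, exc, {"rule": "fixed_indegree", "indegree": 6},
                STDPPowerLawSynapse(weight=20.0, w0=20.0, delay=1.5))
    net.connect(exc, par, {"rule": "fixed_indegree", "indegree": 3},
                StaticSynapse(weight=1.0, delay=1.0))
    net.connect(par, cond, "all_to_all",
                StaticSynapse(weight=1.5, delay=1.5, receptor="AMPA"))
    net.connect(cond, cond, {"rule": "pairwise_gaussian", "p0": 0.5, "sigma": 0.3},
                StaticSynapse(weight=1.0, delay=1.0, receptor="GABA_A"))
    net.connect(drive, cond, syn=StaticSynapse(weight=3.0, delay=1.0,
                                               receptor="AMPA"))
    for pop in (exc, cond, par):
        net.connect(pop, rec)
    return net, rec


@pytest.fixture
def mixed_network():
    return build_mixed_network(1)


def rk4_trajectory(f, y0, t_grid, nsub=100):
    """Dense fixed-step RK4 reference integrator (oracle for the exact
    propagators; independent of the kernel's update path)."""
    ys = []
    y = np.array(y0, dtype=float)
    for i in range(len(t_grid) - 1):
        t0, t1 = t_grid[i], t_grid[i + 1]
        dt = (t1 - t0) / nsub
        t = t0
        for _ in range(nsub):
            k1 = f(t, y)
            k2 = f(t + dt / 2, y + dt / 2 * k1)
            k3 = f(t + dt / 2, y + dt / 2 * k2)
            k4 = f(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        ys.append(y.copy())
    return np.array(ys)
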