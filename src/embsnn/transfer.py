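"""Transfer functions between spike domain and plant domain.

A *spike sink* reads out a population through a leaky integrator neuron
with disabled threshold that receives static synapses from every neuron of
the population; its membrane deflection, normalized by ``v_span`` and
clipped to [0, 1], is a muscle activation signal.  A *spike source* injects
rate-coded drive into a population through Poisson generators connected to
all its neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import Population
from .network import Network
from .params import LIFCurrentParams, StaticSynapse

__all__ = ["SpikeSink", "SpikeSource", "make_spike_sink",
           "read_activation", "make_spike_source", "set_rate"]


@dataclass
class SpikeSink:
    """Population readout mapped onto muscle activation in [0, 1]."""

    readout: Population          # single leaky integrator, V_th = +inf
    source: Population
    muscles: tuple               # target muscle indices
    v_span: float                # mV deflection that saturates activation
    E_L: float


@dataclass
class SpikeSource:
    generator: Population        # Poisson device
    target: Population
    rate: float = 0.0


def make_spike_sink(net: Network, population: Population, muscles=(),
                    weight: float = 10.0, delay: float = 1.0,
                    tau_m: float = 10.0, v_span: float | None = None,
                    reference_rate_hz: float = 8.0) -> SpikeSink:
    """Create a readout neuron and connect the whole population to it.

    ``tau_m`` sets the smoothing window of the integrator; ``v_span`` the
    membrane deflection (mV) mapped to full activation.  When ``v_span`` is
    None it is sized so that the population firing at ``reference_rate_hz``
    drives the sink to about 0.8.
    """
    if population is None or population.count < 1:
        raise ValueError("sink requires a non-empty population")
    p = LIFCurrentParams(tau_m=tau_m)
    if v_span is None:
        # steady-state deflection at the reference rate: each alpha PSC of
        # peak w carries charge w*e*tau_syn, so mean current is
        # count*rate*w*e*tau_syn and dV = (tau_m/C_m) * I_mean
        i_mean = population.count * reference_rate_hz * 1e-3 * weight * np.e * p.tau_syn
        v_span = (p.tau_m / p.C_m) * i_mean / 0.8
    readout = net.create("readout_neuron", 1, p,
                         name=f"sink_of_{population.name or population.first_id}")
    n = net.connect(population, readout, "all_to_all",
                    StaticSynapse(weight=weight, delay=delay))
    assert n == population.count
    return SpikeSink(readout=readout, source=population,
                     muscles=tuple(muscles), v_span=v_span, E_L=p.E_L)


def read_activation(net: Network, sink: SpikeSink) -> float:
    """Clipped, normalized readout voltage: clip((V - E_L)/v_span, 0, 1)."""
    _, v = net.get_voltages(sink.readout)
    return float(np.clip((v[0] - sink.E_L) / sink.v_span, 0.0, 1.0))


def make_spike_source(net: Network, population: Population,
                      weight: float = 2.0, delay: float = 1.0,
                      receptor: str | None = None) -> SpikeSource:
    """Poisson generator wired to every neuron of the target population."""
    gen = net.create("poisson_generator", 1, {"rate": 0.0},
                     name=f"source_to_{population.name or population.first_id}")
    syn = StaticSynapse(weight=weight, delay=delay, receptor=receptor)
    net.connect(gen, population, "all_to_all", syn)
    return SpikeSource(generator=gen, target=population, rate=0.0)


def set_rate(net: Network, source: SpikeSource, rate_hz: float):
    """Set the source rate; takes effect from the next kernel step."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    net.set_status(source.generator, rate=float(rate_hz))
    source.rate = float(rate_hz)
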