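"""Scale-parameterized balanced random network (HPC benchmark model).

The network holds ``round(11250 * scale)`` neurons; the recurrent indegree
of every neuron is fixed at 11,250 synapses regardless of the scale
(9,000 excitatory + 2,250 inhibitory, the 4:1 convention of the benchmark
lineage), so at scales below 1 multapses are frequent by construction.
Excitatory-to-excitatory synapses are plastic (power-law STDP); all
connections touching inhibitory neurons are static.  A single external
Poisson drive device feeds one connection to every neuron; the node and
connection census therefore follows

    nodes       = neurons + 1
    connections = neurons * 11250 + neurons

which reproduces the published scale-20 figures (225,000 neurons, 225,001
nodes, 2,531,475,000 connections) exactly.

Weights, delays and the external drive rate are not published for the
benchmark; they are configuration with documented defaults and are
excluded from every census.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..kernel import Population
from ..network import Network
from ..params import KernelConfig, LIFCurrentParams, STDPPowerLawSynapse, StaticSynapse

__all__ = ["BASE_N", "INDEGREE", "count_brunel", "build_brunel",
           "recurrent_indegrees", "BrunelHandles"]

BASE_N = 11250          # neurons per unit scale
INDEGREE = 11250        # fixed recurrent indegree
E_PER_UNIT = 9000       # excitatory neurons per unit scale
K_E = 9000              # excitatory share of the indegree
K_I = 2250              # inhibitory share

DEFAULT_SYNAPSE_BUDGET = 6_000_000


def count_brunel(scale: float) -> tuple[int, int, int]:
    """Exact dry-run census (neurons, nodes, connections); no instantiation."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    neurons = round(BASE_N * scale)
    nodes = neurons + 1                       # + the external drive device
    connections = neurons * INDEGREE + neurons
    return neurons, nodes, connections


@dataclass
class BrunelHandles:
    net: Network
    exc: Population
    inh: Population
    drive: Population
    recorder: Population | None
    census: tuple[int, int, int]    # instantiated (neurons, nodes, connections)


def build_brunel(scale: float, config: KernelConfig | None = None,
                 w_exc: float = 2.0, g: float = 5.0, delay: float = 1.5,
                 drive_rate: float = 30000.0, stdp_kw: dict | None = None,
                 record: bool = True,
                 synapse_budget: int = DEFAULT_SYNAPSE_BUDGET) -> BrunelHandles:
    """Instantiate the balanced network at the given scale.

    Refuses to build when the dry-run census exceeds ``synapse_budget``
    (full-scale instantiation is a matter for the original HPC deployment,
    not this desk kernel).
    """
    neurons, nodes, connections = count_brunel(scale)
    if connections > synapse_budget:
        raise ValueError(
            f"refusing to instantiate: census {connections:,} connections "
            f"({neurons:,} neurons, {nodes:,} nodes) exceeds the synapse "
            f"budget {synapse_budget:,}"
        )
    n_e = round(E_PER_UNIT * scale)
    n_i = neurons - n_e
    if n_e < 1 or n_i < 1:
        raise ValueError(f"scale {scale} leaves an empty population")
    net = Network(config if config is not None else KernelConfig())

    p = LIFCurrentParams()
    exc = net.create("lif_current", n_e, p, name="E")
    inh = net.create("lif_current", n_i, p, name="I")
    drive = net.create("poisson_generator", 1, {"rate": drive_rate}, name="drive")

    stdp = STDPPowerLawSynapse(weight=w_exc, w0=w_exc, delay=delay,
                               **(stdp_kw or {}))
    exc_syn = StaticSynapse(weight=w_exc, delay=delay)
    inh_syn = StaticSynapse(weight=-g * w_exc, delay=delay)
    n_conn = 0
    n_conn += net.connect(exc, exc, {"rule": "fixed_indegree", "indegree": K_E}, stdp)
    n_conn += net.connect(exc, inh, {"rule": "fixed_indegree", "indegree": K_E}, exc_syn)
    n_conn += net.connect(inh, exc, {"rule": "fixed_indegree", "indegree": K_I}, inh_syn)
    n_conn += net.connect(inh, inh, {"rule": "fixed_indegree", "indegree": K_I}, inh_syn)
    for pop in (exc, inh):
        n_conn += net.connect(drive, pop, "all_to_all",
                              StaticSynapse(weight=w_exc, delay=delay))
    recorder = None
    if record:
        recorder = net.create("spike_recorder", 1, name="spikes")
        net.connect(exc, recorder)
        net.connect(inh, recorder)
    return BrunelHandles(net=net, exc=exc, inh=inh, drive=drive,
                         recorder=recorder,
                         census=(neurons, nodes, n_conn))


def recurrent_indegrees(handles: BrunelHandles) -> np.ndarray:
    """Incoming recurrent synapse count per neuron, from the instantiated
    synapse stores (drive and recorder connections excluded)."""
    neurons = handles.exc.count + handles.inh.count
    first = handles.exc.first_id
    counts = np.zeros(neurons, dtype=np.int64)
    for w in handles.net.workers:
        for proj in w.projections:
            post_gids = proj.post.first_id + (
                w.pops[id(proj.post)]["offsets"][proj.post_local]
            )
            np.add.at(counts, post_gids - first, 1)
    return counts
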