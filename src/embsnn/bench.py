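"""Benchmark harness: the scaling grid and the embodied experiment protocol.

A benchmark plan sweeps worker counts (doubling by default) for a number of
repetitions; each cell builds the requested network from scratch with an
identical seed, runs the closed-loop engine for the configured duration
(50 steps of 20 ms by default) and records build time, per-step profile
and the derived metrics (real-time factor, brain/body step ratio,
node-hours).  Build and brain-step times are critical-path times (max over
logical workers): the wall time a genuinely concurrent deployment of the
same shards would take.

The embodied protocol reproduces the benchmark experiment procedure: a
base activation to all 8 muscles for the first 5 CLE steps, spike-source
rates pinned to 0 every step, the elongated-neurogliaform-cell (ENGC)
source switched to 5000 Hz from step 25, and the ENGC sink driving three
muscles from step 6 onward, while the joystick trajectory and a status
line are logged.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cle import CLEConfig, ClosedLoopEngine, node_hours, real_time_factor, step_ratio
from .network import Network
from .params import KernelConfig
from .plant import Plant
from .transfer import make_spike_sink, make_spike_source, read_activation, set_rate
from .netbuilders import brunel, cbct

log = logging.getLogger("embsnn.bench")

__all__ = ["BenchmarkPlan", "BenchmarkResult", "run_benchmark",
           "EmbodimentBindings", "setup_embodiment", "run_embodied_protocol",
           "nodes_for"]

EXPERIMENT_KINDS = ("brunel", "cbct", "cbct_m1_only")

# three muscles the ENGC readout drives: the "+" muscle of the shoulder
# flexion, elbow and wrist axes (the ones pushing the joystick forward)
ENGC_MUSCLES = (0, 4, 6)
SOURCE_LAYERS = ("M1/L1:ENGC", "M1/L2/3:IT", "M1/L5A:IT")


def nodes_for(n_workers: int) -> int:
    """Compute-node count for a worker count: two simulation workers per
    node plus one node for the orchestrator/plant."""
    return 1 + math.ceil(n_workers / 2)


@dataclass(frozen=True)
class BenchmarkPlan:
    kind: str = "brunel"
    scale: float = 0.02
    worker_counts: tuple = (1, 2, 4)
    repetitions: int = 1
    duration_ms: float = 1000.0
    exchange_interval_ms: float = 20.0
    seed: int = 1

    def __post_init__(self):
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if list(self.worker_counts) != sorted(set(self.worker_counts)):
            raise ValueError("worker counts must be strictly increasing")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class BenchmarkResult:
    plan: BenchmarkPlan
    cells: list = field(default_factory=list)

    COLUMNS = ("rep", "n_workers", "build_s", "last_sim_step_s", "runtime_s",
               "rtf", "step_ratio", "node_hours", "error")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, columns=self.COLUMNS)

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        return pd.read_csv(path)


class _BrainAdapter:
    """CLE brain handle over a network; reports critical-path step time."""

    def __init__(self, net: Network):
        self.net = net

    def advance(self, ms: float) -> float:
        self.net.simulate(ms)
        return float(self.net.last_sim_worker_times.max())


class _PlantAdapter:
    def __init__(self, plant: Plant):
        self.plant = plant
        self.u = np.zeros(8)

    def advance(self, ms: float):
        self.plant.advance(ms, self.u)


def _build(kind: str, scale: float, config: KernelConfig):
    if kind == "brunel":
        handles = brunel.build_brunel(scale, config=config)
        return handles, handles.net
    regions = ("M1",) if kind == "cbct_m1_only" else None
    handles = cbct.build_cbct(scale, config=config, regions=regions)
    return handles, handles.net


def run_benchmark(plan: BenchmarkPlan, outdir=None) -> BenchmarkResult:
    """Run the full (repetition x worker-count) grid; failures are recorded
    per cell and the grid continues."""
    result = BenchmarkResult(plan=plan)
    for rep in range(plan.repetitions):
        for nw in plan.worker_counts:
            cell = {"rep": rep, "n_workers": nw, "error": None}
            try:
                t_start = time.perf_counter()
                config = KernelConfig(seed=plan.seed, n_workers=nw)
                handles, net = _build(plan.kind, plan.scale, config)
                cell["build_s"] = float(net.worker_build_time.max())
                engine, bindings = _make_engine(plan, handles, net)
                if bindings is not None:
                    run_embodied_protocol(engine, bindings)
                else:
                    engine.run()
                prof = engine.profile
                cell["last_sim_step_s"] = prof.brain[-1]
                runtime = time.perf_counter() - t_start
                cell["runtime_s"] = runtime
                cell["rtf"] = real_time_factor(prof, plan.exchange_interval_ms)
                cell["step_ratio"] = step_ratio(prof)
                cell["node_hours"] = node_hours(runtime, nodes_for(nw))
                if outdir is not None and getattr(handles, "recorder", None) is not None:
                    from .io import write_gdf
                    ev = net.get_spikes(handles.recorder)
                    write_gdf(f"{outdir}/spikes_{plan.kind}_rep{rep}_w{nw}.gdf", ev)
                log.info("cell rep=%d workers=%d rtf=%.4g build=%.3gs",
                         rep, nw, cell["rtf"], cell["build_s"])
            except Exception as exc:   # cell failure never kills the grid
                log.warning("cell rep=%d workers=%d failed: %s", rep, nw, exc)
                cell["error"] = str(exc)
            result.cells.append({c: cell.get(c) for c in BenchmarkResult.COLUMNS})
    if outdir is not None:
        result.write_csv(f"{outdir}/benchmark_{plan.kind}.csv")
    return result


def _make_engine(plan: BenchmarkPlan, handles, net):
    cle_cfg = CLEConfig(exchange_interval=plan.exchange_interval_ms,
                        total_duration=plan.duration_ms)
    plant = _PlantAdapter(Plant())
    brain = _BrainAdapter(net)
    if plan.kind == "brunel":
        # unconnected plant serves as base workload, mirroring the
        # balanced-network benchmark setup
        return ClosedLoopEngine(brain, plant, transfers=(), config=cle_cfg), None
    bindings = setup_embodiment(handles, net)
    engine = ClosedLoopEngine(brain, plant, transfers=(), config=cle_cfg)
    return engine, bindings


# ---- embodied protocol --------------------------------------------------


@dataclass
class EmbodimentBindings:
    sinks: dict              # "REGION/layer:type" -> SpikeSink (all M1 layers)
    engc_sink: object
    sources: dict            # population key -> SpikeSource
    base_activation: float = 0.2


def setup_embodiment(handles, net: Network) -> EmbodimentBindings:
    """ENGC sink on three muscles, inspection sinks for every M1 layer,
    Poisson sources on three M1 layers including the ENGC."""
    if "M1/L1:ENGC" not in handles.by_key:
        raise ValueError("embodiment requires the M1 region (ENGC population)")
    sinks = {}
    seen_layers = set()
    for key, pops in handles.by_key.items():
        region, rest = key.split("/", 1)
        layer = rest.split(":")[0]
        if region != "M1" or layer in seen_layers:
            continue
        seen_layers.add(layer)
        sinks[key] = make_spike_sink(net, pops[0], reference_rate_hz=40.0)
    engc = handles.by_key["M1/L1:ENGC"][0]
    # 40 Hz reference leaves the resting cortex at low activation and the
    # 5 kHz-driven ENGC near saturation
    engc_sink = make_spike_sink(net, engc, muscles=ENGC_MUSCLES,
                                reference_rate_hz=40.0)
    sources = {k: make_spike_source(net, handles.by_key[k][0])
               for k in SOURCE_LAYERS if k in handles.by_key}
    return EmbodimentBindings(sinks=sinks, engc_sink=engc_sink, sources=sources)


def run_embodied_protocol(engine: ClosedLoopEngine,
                          bindings: EmbodimentBindings) -> pd.DataFrame:
    """Stepwise experiment: 5 base-activation steps, sources pinned to 0
    every step, ENGC source at 5000 Hz from step 25, sink-driven muscles
    from step 6.  Returns the joystick/activation trajectory."""
    net = engine.brain.net
    plant_ad = engine.plant
    rows = []
    plant_ad.u = np.full(8, bindings.base_activation)   # step 1 excitation
    state = {"rate": 0.0}                               # rate active this step

    def transfer(eng):
        k = eng.steps_done + 1           # CLE step just completed (1-based)
        act = read_activation(net, bindings.engc_sink)
        fwd, lat = plant_ad.plant.joystick_angles()
        rows.append({"step": k,
                     "t_ms": eng.sim_time + eng.config.exchange_interval,
                     "engc_activation": act, "forward_rad": fwd,
                     "lateral_rad": lat, "engc_rate": state["rate"]})
        if k >= 5:
            log.info("step %d: network input %s, ENGC activation %.3f",
                     k, "ON (5000 Hz)" if state["rate"] > 0 else "off", act)
        # program the next step: every source is pinned to rate 0 on every
        # iteration except the ENGC source from step 25 onward
        k_next = k + 1
        rate_next = 5000.0 if k_next >= 25 else 0.0
        for key, src in bindings.sources.items():
            set_rate(net, src, rate_next if key == "M1/L1:ENGC" else 0.0)
        state["rate"] = rate_next
        if k_next <= 5:
            u = np.full(8, bindings.base_activation)
        else:
            u = np.zeros(8)
            for m in bindings.engc_sink.muscles:
                u[m] = act
        plant_ad.u = u

    engine.transfers = [transfer]
    engine.run()
    return pd.DataFrame(rows)
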