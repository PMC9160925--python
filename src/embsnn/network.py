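"""Lockstep orchestration of logical workers and the user-facing network API.

A :class:`Network` owns ``n_workers`` :class:`~embsnn.kernel.Worker` shards,
allocates global ids, broadcasts construction calls, and advances all shards
in lockstep, exchanging spikes once per resolution step.  Because every
random draw is keyed to global entity ids, the spike output of a network is
bitwise identical for any worker count; the sharding affects only where
state lives and how work is apportioned.
"""

from __future__ import annotations

import time

import numpy as np

from .kernel import MODEL_KINDS, Population, Worker
from .params import (
    KernelConfig,
    LIFConductanceParams,
    LIFCurrentParams,
    STDPPowerLawSynapse,
    StaticSynapse,
)

__all__ = ["Network"]

_EVENT_DTYPE = np.dtype([("gid", np.int64), ("t", np.float64)])


class Network:
    """A spiking network distributed over logical workers."""

    def __init__(self, config: KernelConfig | None = None, **kw):
        self.config = config if config is not None else KernelConfig(**kw)
        self.workers = [Worker(self.config, w) for w in range(self.config.n_workers)]
        self._next_gid = 1
        self._conn_id = 0
        self.step = 0
        self._pending = (np.empty(0, np.int64),) * 3
        self.populations: list[Population] = []
        # per-worker wall-time bookkeeping (critical-path benchmark metrics)
        self.worker_build_time = np.zeros(self.config.n_workers)
        self.last_sim_worker_times = np.zeros(self.config.n_workers)

    # ---- construction -------------------------------------------------

    def create(self, model: str, n: int, params=None, positions=None,
               name=None, bias=None, v_init=None) -> Population:
        """Create ``n`` nodes of a registered model kind.

        Returns a :class:`Population` with fresh, contiguous global ids.
        Neuron membrane potentials start at ``E_L`` unless ``v_init`` is
        given (one value per neuron).
        """
        if model not in MODEL_KINDS:
            raise ValueError(f"unknown model kind: {model!r}")
        if n < 1:
            raise ValueError("n must be >= 1")
        params = self._coerce_params(model, params)
        pop = Population(self._next_gid, int(n), model, params,
                         positions=positions, name=name)
        self._next_gid += int(n)
        for w in self.workers:
            t0 = time.perf_counter()
            w.create(pop, bias=bias, v_init=v_init)
            self.worker_build_time[w.worker_id] += time.perf_counter() - t0
        self.populations.append(pop)
        return pop

    @staticmethod
    def _coerce_params(model, params):
        if params is None or not isinstance(params, dict):
            return params
        if model in ("lif_current", "readout_neuron"):
            return LIFCurrentParams(**params)
        if model == "lif_conductance":
            params = dict(params)
            if "receptors" in params:
                from .params import Receptor
                params["receptors"] = tuple(
                    r if isinstance(r, Receptor) else
                    (Receptor(**r) if isinstance(r, dict) else Receptor(*r))
                    for r in params["receptors"]
                )
            return LIFConductanceParams(**params)
        return params

    def connect(self, pre: Population, post: Population, rule="all_to_all",
                syn=None) -> int:
        """Connect two populations; returns the exact number of synapses."""
        if isinstance(rule, str):
            rule = {"rule": rule}
        if isinstance(syn, dict):
            syn = (STDPPowerLawSynapse(**syn) if syn.pop("stdp", False)
                   else StaticSynapse(**syn))
        conn_id = self._conn_id
        self._conn_id += 1
        total = 0
        for w in self.workers:
            t0 = time.perf_counter()
            total += w.connect(pre, post, rule, syn, conn_id)
            self.worker_build_time[w.worker_id] += time.perf_counter() - t0
        return total

    # ---- simulation ---------------------------------------------------

    def simulate(self, duration: float):
        """Advance the network by ``duration`` ms (a multiple of the resolution)."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        steps = self.config.steps(duration)
        wt = np.zeros(self.config.n_workers)
        for _ in range(steps):
            outs = []
            for w in self.workers:
                t0 = time.perf_counter()
                w.route(*self._pending)
                out = w.advance()
                wt[w.worker_id] += time.perf_counter() - t0
                outs.append(out)
            self._pending = self._merge(outs)
        self.step += steps
        self.last_sim_worker_times = wt

    @staticmethod
    def _merge(outs):
        stamps = np.concatenate([o[0] for o in outs])
        gids = np.concatenate([o[1] for o in outs])
        counts = np.concatenate([o[2] for o in outs])
        if len(gids) > 1:
            order = np.lexsort((gids, stamps))
            stamps, gids, counts = stamps[order], gids[order], counts[order]
        return stamps, gids, counts

    @property
    def time(self) -> float:
        """Current kernel time in ms."""
        return self.step * self.config.resolution

    # ---- inspection ---------------------------------------------------

    def get_spikes(self, recorder: Population, t_from: float | None = None,
                   t_to: float | None = None) -> np.ndarray:
        """Recorded events merged over workers, sorted by (t, gid).

        The window is half-open: ``t_from <= t < t_to``.  The result is a
        structured array with fields ``gid`` and ``t`` and is identical for
        any worker count.
        """
        if t_from is not None and t_to is not None and t_from > t_to:
            raise ValueError("inverted time window")
        parts = [w.recorded(recorder) for w in self.workers]
        stamps = np.concatenate([p[0] for p in parts])
        gids = np.concatenate([p[1] for p in parts])
        counts = np.concatenate([p[2] for p in parts])
        gids = np.repeat(gids, counts)
        times = np.repeat(stamps, counts) * self.config.resolution
        ev = np.empty(len(gids), dtype=_EVENT_DTYPE)
        ev["gid"], ev["t"] = gids, times
        ev = ev[np.lexsort((ev["gid"], ev["t"]))]
        if t_from is not None:
            ev = ev[ev["t"] >= t_from - 1e-9]
        if t_to is not None:
            ev = ev[ev["t"] < t_to - 1e-9]
        return ev

    def get_voltages(self, pop: Population):
        """(gids, V_m) for a neuron population, merged in gid order."""
        parts = [w.get_voltages(pop) for w in self.workers]
        gids = np.concatenate([p[0] for p in parts])
        V = np.concatenate([p[1] for p in parts])
        order = np.argsort(gids)
        return gids[order], V[order]

    def mean_rate(self, recorder: Population, n_neurons: int,
                  t_from: float, t_to: float) -> float:
        """Population mean firing rate in Hz over [t_from, t_to) ms."""
        ev = self.get_spikes(recorder, t_from, t_to)
        return len(ev) / (n_neurons * (t_to - t_from) * 1e-3)

    def set_status(self, pop: Population, **kw):
        """Set mutable device parameters (e.g. a Poisson generator's rate)."""
        for w in self.workers:
            w.set_device_params(pop, **kw)

    def get_population_parameters(self, pop: Population):
        return pop.params

    def kernel_status(self) -> dict:
        """Combined kernel status: shared scalars plus summed local counters."""
        per = [w.kernel_status() for w in self.workers]
        out = dict(per[0])
        out["num_neurons"] = sum(p["local_num_neurons"] for p in per)
        out["num_connections"] = sum(p["local_num_connections"] for p in per)
        return out

    def worker_statuses(self) -> list[dict]:
        return [w.kernel_status() for w in self.workers]
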