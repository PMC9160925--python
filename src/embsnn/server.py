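"""Master-worker simulation-control plane.

One master owns the API surface, broadcasts each command to all logical
workers (the master itself participates in the simulation as worker 0), and
combines the per-worker responses into a single consistent view, so a
caller cannot tell how many workers served the request.

Combination is governed by an *explicit* per-endpoint registry rather than
type guessing: identical scalars collapse to the scalar, registered
additive fields (counts of locally owned entities) are summed, event lists
are merge-sorted by (t, gid), and records are combined field-wise.
Contradictory non-additive values raise :class:`DivergenceError` instead of
being silently masked.

Two interchangeable bindings are provided: in-process (:class:`SimServer`
used directly) and JSON-over-HTTP (``POST /api/<Endpoint>``, default port
5000) via :func:`serve_http` and :class:`HTTPClient`.
"""

from __future__ import annotations

import json
import threading
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.request import Request, urlopen

import numpy as np

from .io import build_from_description
from .network import Network
from .params import KernelConfig

__all__ = ["SimServer", "CombinedResponse", "DivergenceError",
           "serve_http", "HTTPClient"]

ENDPOINTS = ("Create", "Connect", "Simulate", "GetKernelStatus",
             "SetStatus", "GetStatus", "LoadNetwork")

# fields summed across workers, per endpoint; everything else must agree
ADDITIVE_FIELDS = {
    "Create": {"local_count"},
    "Connect": {"connections"},
    "GetKernelStatus": {"local_num_neurons", "local_num_connections"},
    "GetStatus": set(),
    "Simulate": set(),
    "SetStatus": set(),
    "LoadNetwork": {"local_num_neurons", "local_num_connections"},
}
EVENT_FIELDS = {"events"}


class DivergenceError(RuntimeError):
    """Workers returned non-combinable responses for a non-additive field."""


@dataclass
class CombinedResponse:
    value: object
    provenance: list    # raw per-worker responses, retained for audit


def combine(responses: list, endpoint: str):
    """Combine one response per worker into a single consistent value."""
    if endpoint not in ADDITIVE_FIELDS:
        raise ValueError(f"unknown endpoint: {endpoint!r}")
    return _combine(responses, ADDITIVE_FIELDS[endpoint], field=None)


def _combine(values, additive, field):
    first = values[0]
    if isinstance(first, dict):
        if field in EVENT_FIELDS:
            return _merge_events(values)
        return {k: _combine([v[k] for v in values], additive, k) for k in first}
    if field in additive:
        return sum(values)
    for v in values[1:]:
        if v != first:
            raise DivergenceError(
                f"workers diverge on field {field!r}: {values}"
            )
    return first


def _merge_events(parts):
    gids = np.concatenate([np.asarray(p["gids"], dtype=np.int64) for p in parts])
    times = np.concatenate([np.asarray(p["times"], dtype=float) for p in parts])
    order = np.lexsort((gids, times))
    return {"gids": gids[order].tolist(), "times": times[order].tolist()}


class SimServer:
    """In-process master-worker control plane over one :class:`Network`."""

    def __init__(self, n_workers: int = 1, config: KernelConfig | None = None):
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        self.config = config if config is not None else KernelConfig(n_workers=n_workers)
        if self.config.n_workers != n_workers and config is None:
            raise ValueError("inconsistent worker count")
        self.net: Network | None = None
        self._pops: dict = {}
        self._started = False

    # ---- lifecycle ----------------------------------------------------

    def start(self):
        if self._started:
            raise RuntimeError("server already started")
        self.net = Network(self.config)
        self._pops = {}
        self._started = True
        return self

    def stop(self):
        self._started = False
        self.net = None

    @property
    def n_workers(self) -> int:
        return self.config.n_workers

    # ---- API ----------------------------------------------------------

    def call(self, endpoint: str, payload: dict | None = None) -> CombinedResponse:
        """Broadcast a command; returns the combined per-worker responses."""
        if not self._started:
            raise RuntimeError("server not started")
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint: {endpoint!r}")
        payload = payload or {}
        handler = getattr(self, f"_do_{endpoint.lower()}")
        per_worker = handler(payload)
        value = combine(per_worker, endpoint)
        return CombinedResponse(value=value, provenance=per_worker)

    # Each handler executes the operation through the coordinating network
    # (clocks only ever advance inside Simulate) and then assembles one raw
    # response per worker from that worker's local view.

    def _pop(self, token):
        try:
            return self._pops[token]
        except KeyError:
            raise ValueError(f"unknown population {token!r}") from None

    def _do_create(self, p):
        pop = self.net.create(
            p["model"], int(p["n"]), params=p.get("params"),
            name=p.get("name"), positions=p.get("positions"),
        )
        token = p.get("name", f"pop{len(self._pops)}")
        self._pops[token] = pop
        return [
            {"pop": token, "first_id": pop.first_id, "count": pop.count,
             "model": pop.model,
             "local_count": int((pop.gids % self.n_workers == w.worker_id).sum())}
            for w in self.net.workers
        ]

    def _do_connect(self, p):
        pre, post = self._pop(p["pre"]), self._pop(p["post"])
        before = [w.n_local_connections for w in self.net.workers]
        self.net.connect(pre, post, rule=p.get("rule", "all_to_all"),
                         syn=dict(p["syn"]) if p.get("syn") else None)
        return [
            {"connections": w.n_local_connections - b}
            for w, b in zip(self.net.workers, before)
        ]

    def _do_simulate(self, p):
        self.net.simulate(float(p["duration"]))
        return [{"time": w.step * w.h} for w in self.net.workers]

    def _do_getkernelstatus(self, p):
        return [w.kernel_status() for w in self.net.workers]

    def _do_setstatus(self, p):
        pop = self._pop(p["pop"])
        params = dict(p.get("params", {}))
        self.net.set_status(pop, **params)
        return [{"ok": True} for _ in self.net.workers]

    def _do_getstatus(self, p):
        pop = self._pop(p["pop"])
        if pop.model == "spike_recorder":
            out = []
            for w in self.net.workers:
                stamps, gids, counts = w.recorded(pop)
                g = np.repeat(gids, counts)
                t = np.repeat(stamps, counts) * self.config.resolution
                out.append({"events": {"gids": g.tolist(), "times": t.tolist()}})
            return out
        return [
            {"gids": g.tolist(), "V_m": v.tolist()}
            for g, v in (w.get_voltages(pop) for w in self.net.workers)
        ]

    def _do_loadnetwork(self, p):
        # descriptions only (rules + parameter records), never arbitrary code
        net, pops = build_from_description(p["description"], config=self.config)
        self.net, self._pops = net, pops
        return [
            {"populations": len(pops),
             "local_num_neurons": w.n_local_neurons,
             "local_num_connections": w.n_local_connections}
            for w in net.workers
        ]


# ---- HTTP binding ------------------------------------------------------


def serve_http(server: SimServer, port: int = 5000, host: str = "127.0.0.1"):
    """Expose a started :class:`SimServer` as POST /api/<Endpoint> (JSON).

    Returns the underlying ``ThreadingHTTPServer``; call ``shutdown()`` on
    it to stop serving.
    """

    class Handler(BaseHTTPRequestHandler):
        def do_POST(self):
            if not self.path.startswith("/api/"):
                self.send_error(404)
                return
            endpoint = self.path[len("/api/"):]
            n = int(self.headers.get("Content-Length", 0))
            payload = json.loads(self.rfile.read(n) or b"{}")
            try:
                resp = server.call(endpoint, payload)
                body = json.dumps(
                    {"value": resp.value, "provenance": resp.provenance}
                ).encode()
                code = 200
            except (ValueError, KeyError, RuntimeError, DivergenceError) as exc:
                body = json.dumps({"error": str(exc)}).encode()
                code = 400
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, *a):   # quiet
            pass

    httpd = ThreadingHTTPServer((host, port), Handler)
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    httpd._thread = thread
    return httpd


class HTTPClient:
    """Thin JSON client mirroring the in-process ``call`` interface."""

    def __init__(self, host: str = "127.0.0.1", port: int = 5000):
        self.base = f"http://{host}:{port}/api/"

    def call(self, endpoint: str, payload: dict | None = None) -> CombinedResponse:
        req = Request(
            self.base + endpoint,
            data=json.dumps(payload or {}).encode(),
            headers={"Content-Type": "application/json"},
        )
        with urlopen(req) as fh:
            out = json.loads(fh.read())
        return CombinedResponse(value=out["value"], provenance=out["provenance"])
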