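"""Readers and writers for the package's text formats.

* spike files: GDF-like two-column whitespace text ``gid time_ms``, one
  event per line, sorted by (time, gid);
* network descriptions: a YAML schema listing populations, parameter
  records and connectivity *rules* (never instantiated synapse lists), so a
  description re-instantiates bit-identically under the same master seed.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from . import rng
from .network import Network, _EVENT_DTYPE
from .params import KernelConfig

__all__ = [
    "write_gdf",
    "read_gdf",
    "dump_network",
    "load_network",
    "build_from_description",
]


def write_gdf(path, events: np.ndarray):
    """Write spike events (structured array with fields gid, t) as GDF text."""
    path = Path(path)
    with path.open("w") as fh:
        for ev in events:
            fh.write(f"{int(ev['gid'])}\t{float(ev['t']):.3f}\n")


def read_gdf(path) -> np.ndarray:
    """Read a GDF spike file into a (gid, t) structured array."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            g, t = line.split()
            rows.append((int(g), float(t)))
    ev = np.array(rows, dtype=_EVENT_DTYPE)
    return ev[np.lexsort((ev["gid"], ev["t"]))]


def _params_to_dict(params):
    if params is None:
        return None
    if is_dataclass(params):
        d = asdict(params)
        if "receptors" in d:
            d["receptors"] = [
                [r["label"], float(r["E_rev"]), float(r["tau"])]
                for r in d["receptors"]
            ]
        return d
    return dict(params)


def dump_network(description: dict, path):
    """Serialize a network description (populations + rules) to YAML."""
    desc = dict(description)
    pops = []
    for p in desc.get("populations", []):
        p = dict(p)
        if "params" in p:
            p["params"] = _params_to_dict(p["params"])
        pops.append(p)
    desc["populations"] = pops
    with Path(path).open("w") as fh:
        yaml.safe_dump(desc, fh, sort_keys=False)


def load_network(path) -> dict:
    """Load a network description from YAML."""
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def build_from_description(desc: dict, config: KernelConfig | None = None):
    """Instantiate a description; returns (network, {name: population}).

    ``config`` overrides the description's kernel record (e.g. to change
    the worker count without touching the network definition).
    """
    if config is None:
        config = KernelConfig(**desc.get("kernel", {}))
    net = Network(config)
    pops = {}
    for p in desc.get("populations", []):
        positions = p.get("positions")
        if isinstance(positions, dict):
            extent = float(positions["extent_mm"])
            # keyed generation: identical placement for any worker count
            u = rng.uniform(
                config.seed, rng.PURPOSE["positions"],
                np.arange(p["count"], dtype=np.int64) + net._next_gid,
                np.array([0, 1], dtype=np.int64)[:, None],
            )
            positions = (u.T * extent)
        pop = net.create(
            p["model"], p["count"], params=p.get("params"),
            positions=positions, name=p.get("name"),
            bias=p.get("bias"), v_init=p.get("v_init"),
        )
        pops[p.get("name", f"pop{len(pops)}")] = pop
    for c in desc.get("connections", []):
        syn = dict(c.get("syn") or {})
        net.connect(pops[c["pre"]], pops[c["post"]], rule=c.get("rule", "all_to_all"),
                    syn=syn or None)
    return net, pops
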