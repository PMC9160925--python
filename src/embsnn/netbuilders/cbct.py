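"""Multi-region cortico-basal ganglia-cerebellar-thalamic (CBCT) builder.

Populations live on 1x1 mm^2 sheets with uniformly drawn positions;
intra-region wiring uses distance-dependent Gaussian kernels; the ten
published inter-regional pathways are topographic (every post neuron links
to its nearest presynaptic sheet coordinate plus Gaussian-sampled spread),
with parrot relays inserted at the cortical-output and thalamocortical
interfaces.  Conductance-based neurons receive bias currents drawn per
neuron from population-specific normal distributions; the Pons
(mossy-fiber) population is driven by a calibrated Poisson input instead,
targeting the published 8 Hz resting rate.

The region composition is packaged in ``data/cbct_composition.yaml`` and
reproduces the published regional totals exactly (1,005,905 neurons at
scale 1); all dynamic parameters live in ``data/cbct_params.yaml`` and are
this package's own documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .. import rng
from . import place_neurons_2d
from ..kernel import Population
from ..network import Network
from ..params import KernelConfig, LIFConductanceParams, StaticSynapse

__all__ = [
    "load_composition", "load_params", "census_cbct", "build_cbct",
    "build_cerebellum", "CBCTHandles", "ALL_REGIONS", "PATHWAY_NAMES",
]

ALL_REGIONS = ("M1", "S1", "VL", "VM", "BG", "CB_M1", "CB_S1")

# the ten published inter-regional pathways; each expands to one or two
# topographic projections (one per cerebellar module / thalamic zone)
PATHWAY_NAMES = (
    "M1 L5A to BG Striatum",
    "S1 L5A to BG Striatum",
    "BG GPi/SNr to TH",
    "M1 L5B to CB Pons",
    "S1 L5B to CB Pons",
    "CB deep cerebellar nucleus to TH",
    "M1 L6 to TH",
    "S1 L6 to TH",
    "TH to L2/3 M1",
    "TH to L4 S1",
)

# legs: (pre population key, post population key, receptor, relay?)
_PATHWAY_LEGS = {
    "M1 L5A to BG Striatum": [("M1/L5A:IT", "BG/StriatumMSN:MSN", "AMPA", True)],
    "S1 L5A to BG Striatum": [("S1/L5A:IT", "BG/StriatumMSN:MSN", "AMPA", True)],
    "BG GPi/SNr to TH": [
        ("BG/GPiSNr:GPi_SNr", "VL/zoneBG:TC", "GABA_A", False),
        ("BG/GPiSNr:GPi_SNr", "VM/zoneBG:TC", "GABA_A", False),
    ],
    "M1 L5B to CB Pons": [("M1/L5B:PT", "CB_M1/pons:MF", "AMPA", True)],
    "S1 L5B to CB Pons": [("S1/L5B:PT", "CB_S1/pons:MF", "AMPA", True)],
    "CB deep cerebellar nucleus to TH": [
        ("CB_M1/dcn:DCN", "VL/zoneCB:TC", "AMPA", False),
        ("CB_S1/dcn:DCN", "VM/zoneCB:TC", "AMPA", False),
    ],
    "M1 L6 to TH": [
        ("M1/L6:CT", "VL/zoneCB:TC", "AMPA", False),
        ("M1/L6:CT", "VL/zoneBG:TC", "AMPA", False),
    ],
    "S1 L6 to TH": [
        ("S1/L6:CT", "VM/zoneCB:TC", "AMPA", False),
        ("S1/L6:CT", "VM/zoneBG:TC", "AMPA", False),
    ],
    "TH to L2/3 M1": [
        ("VL/zoneCB:TC", "M1/L2/3:IT", "AMPA", True),
        ("VL/zoneBG:TC", "M1/L2/3:IT", "AMPA", True),
    ],
    "TH to L4 S1": [
        ("VM/zoneCB:TC", "S1/L4:IT", "AMPA", True),
        ("VM/zoneBG:TC", "S1/L4:IT", "AMPA", True),
    ],
}


def _data(name: str) -> dict:
    with resources.files("embsnn").joinpath("data", name).open() as fh:
        return yaml.safe_load(fh)


def load_composition() -> dict:
    return _data("cbct_composition.yaml")


def load_params() -> dict:
    return _data("cbct_params.yaml")


# ---- census -------------------------------------------------------------


def _scaled(count: int, scale: float) -> int:
    return round(count * scale)          # round-half-even per population


def census_cbct(scale: float = 1.0, composition: dict | None = None) -> dict:
    """Pure arithmetic on the composition table; scale 1 reproduces the
    published summary exactly."""
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    comp = composition if composition is not None else load_composition()
    regions: dict[str, int] = {}
    per_population = {}
    layers = set()
    for row in comp["populations"]:
        c = _scaled(row["count"], scale)
        key = f"{row['region']}/{row['layer']}:{row['type']}"
        per_population[key] = c
        regions[row["region"]] = regions.get(row["region"], 0) + c
        layers.add((row["region"], row["layer"]))
    meta = comp["regions"]
    return {
        "scale": scale,
        "per_population": per_population,
        "regions": regions,
        "total_neurons": sum(regions.values()),
        "n_layers": sum(m["layers"] for m in meta.values()),
        "n_types": sum(m["types"] for m in meta.values()),
        "n_layers_from_rows": len(layers),
    }


# ---- construction -------------------------------------------------------


@dataclass
class CBCTHandles:
    net: Network
    pops: dict                       # "REGION/layer:type" (or ":sheetK") -> Population
    by_key: dict                     # row key -> list of sheet populations
    recorder: Population | None
    census: dict
    pathways: dict = field(default_factory=dict)   # pathway name -> synapse count
    relays: list = field(default_factory=list)     # parrot interface populations
    drives: dict = field(default_factory=dict)     # region -> poisson generator
    n_neurons_built: int = 0
    n_devices: int = 0

    def rate(self, key: str, t_from: float, t_to: float) -> float:
        """Mean firing rate (Hz) of a composition row over a window."""
        pops = self.by_key[key]
        ev = self.net.get_spikes(self.recorder, t_from, t_to)
        n = 0
        total = 0
        for pop in pops:
            n += pop.count
            sel = (ev["gid"] >= pop.first_id) & (ev["gid"] <= pop.last_id)
            total += int(sel.sum())
        return total / (n * (t_to - t_from) * 1e-3)


def _split_sheets(count: int, sheets: int) -> list[int]:
    base, rem = divmod(count, sheets)
    return [base + (1 if i < rem else 0) for i in range(sheets)]


def build_cbct(scale: float, config: KernelConfig | None = None,
               regions=None, record: bool = True,
               params: dict | None = None,
               composition: dict | None = None) -> CBCTHandles:
    """Instantiate the (sub)model at the given proportional scale.

    ``regions`` restricts the build (e.g. ``("M1",)`` for the motor-cortex
    benchmark variant or ``("CB_M1",)`` for one cerebellar module);
    inter-regional pathways are instantiated whenever both endpoint
    regions are present.
    """
    comp = composition if composition is not None else load_composition()
    par = params if params is not None else load_params()
    regions = tuple(regions) if regions is not None else ALL_REGIONS
    for r in regions:
        if r not in ALL_REGIONS:
            raise ValueError(f"unknown region {r!r}")
    census = census_cbct(scale, comp)
    net = Network(config if config is not None else KernelConfig())
    seed = net.config.seed
    extent = float(par["sheet_extent_mm"])
    nd = par["neuron_defaults"]
    bias_tbl = par["bias_currents"]

    handles = CBCTHandles(net=net, pops={}, by_key={}, recorder=None,
                          census=census)

    for row in comp["populations"]:
        if row["region"] not in regions:
            continue
        key = f"{row['region']}/{row['layer']}:{row['type']}"
        total = census["per_population"][key]
        if total < 1:
            raise ValueError(f"scale {scale} empties population {key}")
        sheets = int(row.get("sheets", 1))
        handles.by_key[key] = []
        p = LIFConductanceParams(**nd["exc" if row["ei"] == "E" else "inh"])
        b = bias_tbl.get(row["type"], bias_tbl["default"])
        for s, c in enumerate(_split_sheets(total, sheets)):
            name = key if sheets == 1 else f"{key}:sheet{s}"
            pos = place_neurons_2d(c, extent, seed, stream_key=net._next_gid)
            gids = np.arange(c, dtype=np.int64) + net._next_gid
            bias = b["mean"] + b["sd"] * rng.normal(
                seed, rng.PURPOSE["bias_current"], gids
            )
            pop = net.create("lif_conductance", c, p, positions=pos,
                             name=name, bias=bias)
            handles.pops[name] = pop
            handles.by_key[key].append(pop)
            handles.n_neurons_built += c

    # --- intra-region wiring -------------------------------------------
    gc = par["gaussian_classes"]

    def gauss(pre_key, post_key, cls):
        for pre in handles.by_key.get(pre_key, []):
            for post in handles.by_key.get(post_key, []):
                c = gc[cls]
                net.connect(
                    pre, post,
                    {"rule": "pairwise_gaussian", "p0": c["p0"], "sigma": c["sigma"]},
                    StaticSynapse(weight=c["weight"], delay=c["delay"],
                                  receptor=c["receptor"]),
                )

    for region in regions:
        rows = [r for r in comp["populations"] if r["region"] == region]
        if region in ("M1", "S1"):
            _wire_cortex(region, rows, gauss)
        elif region in ("VL", "VM"):
            _wire_thalamus(region, rows, gauss)
        elif region == "BG":
            _wire_basal_ganglia(gauss)
        else:
            _wire_cerebellum(region, gauss)

    # --- Pons Poisson drive --------------------------------------------
    drive_par = par["pons_drive"]
    for region in regions:
        if not region.startswith("CB_"):
            continue
        mf_key = f"{region}/pons:MF"
        gen = net.create("poisson_generator", 1,
                         {"rate": float(drive_par["rate"])},
                         name=f"{region}_pons_drive")
        for pop in handles.by_key[mf_key]:
            net.connect(gen, pop, "all_to_all",
                        StaticSynapse(weight=float(drive_par["weight"]),
                                      delay=1.0, receptor="AMPA"))
        handles.drives[region] = gen
        handles.n_devices += 1

    # --- inter-regional topographic pathways ---------------------------
    topo = par["topographic"]
    relay_delay = float(par["relay_delay"])
    for pname in PATHWAY_NAMES:
        legs = _PATHWAY_LEGS[pname]
        n_total = 0
        present = False
        for pre_key, post_key, receptor, use_relay in legs:
            if pre_key not in handles.by_key or post_key not in handles.by_key:
                continue
            present = True
            for pre in handles.by_key[pre_key]:
                for post in handles.by_key[post_key]:
                    src = pre
                    if use_relay:
                        relay = net.create(
                            "parrot", pre.count, positions=pre.positions,
                            name=f"relay:{pre.name}->{post.name}")
                        net.connect(pre, relay, "one_to_one",
                                    StaticSynapse(delay=relay_delay))
                        handles.relays.append(relay)
                        handles.n_devices += pre.count
                        src = relay
                    n_total += _topographic_connect(
                        net, src, post, p0=topo["p0"], sigma=topo["sigma"],
                        weight=topo["weight"], delay=topo["delay"],
                        receptor=receptor)
        if present:
            handles.pathways[pname] = n_total

    if record:
        rec = net.create("spike_recorder", 1, name="spikes")
        for pop in handles.pops.values():
            net.connect(pop, rec)
        handles.recorder = rec
    return handles


def build_cerebellum(scale: float, config: KernelConfig | None = None,
                     **kw) -> CBCTHandles:
    """One cerebellar corticonuclear microcomplex (the M1 module)."""
    return build_cbct(scale, config=config, regions=("CB_M1",), **kw)


def _topographic_connect(net, pre, post, p0, sigma, weight, delay, receptor):
    """Nearest-sheet-coordinate targeting plus Gaussian-sampled spread."""
    tree = cKDTree(pre.positions)
    _, nearest = tree.query(post.positions)
    syn = StaticSynapse(weight=weight, delay=delay, receptor=receptor)
    n = net.connect(post=post, pre=pre, syn=syn, rule={
        "rule": "explicit_pairs",
        "pre_offsets": np.asarray(nearest, dtype=np.int64),
        "post_offsets": np.arange(post.count, dtype=np.int64),
    })
    n += net.connect(pre, post,
                     {"rule": "pairwise_gaussian", "p0": p0, "sigma": sigma},
                     syn)
    return n


# ---- per-region wiring recipes -----------------------------------------


def _wire_cortex(region, rows, gauss):
    layers: dict[str, dict[str, list]] = {}
    for r in rows:
        layers.setdefault(r["layer"], {"E": [], "I": []})[r["ei"]].append(
            f"{region}/{r['layer']}:{r['type']}")
    for lname, d in layers.items():
        for pre in d["E"]:
            for post in d["E"]:
                gauss(pre, post, "cortex_EE")
            for post in d["I"]:
                gauss(pre, post, "cortex_EI")
        for pre in d["I"]:
            for post in d["E"]:
                gauss(pre, post, "cortex_IE")
            for post in d["I"]:
                gauss(pre, post, "cortex_II")
    ff = [("L2/3", "L5A"), ("L2/3", "L5B"), ("L5A", "L5B"), ("L5B", "L6")]
    if region == "S1":
        ff = [("L4", "L2/3"), ("L4add", "L2/3")] + ff
    for pre_l, post_l in ff:
        if pre_l in layers and post_l in layers:
            for pre in layers[pre_l]["E"]:
                for post in layers[post_l]["E"]:
                    gauss(pre, post, "cortex_ff")


def _wire_thalamus(region, rows, gauss):
    for zone in ("zoneCB", "zoneBG"):
        tc = f"{region}/{zone}:TC"
        inn = f"{region}/{zone}:IN"
        rt = f"{region}/{zone}:RT"
        gauss(tc, rt, "th_tc_excite")
        gauss(tc, inn, "th_tc_excite")
        gauss(rt, tc, "th_internal")
        gauss(inn, tc, "th_internal")
        gauss(rt, rt, "th_internal")


def _wire_basal_ganglia(gauss):
    msn = "BG/StriatumMSN:MSN"
    fsi = "BG/StriatumFSI:FSI"
    gpe = "BG/GPe:GPe"
    gpi = "BG/GPiSNr:GPi_SNr"
    stn = "BG/STN:STN"
    gauss(msn, msn, "bg_inhib")
    gauss(fsi, msn, "bg_inhib")
    gauss(msn, gpe, "bg_inhib")
    gauss(msn, gpi, "bg_inhib")
    gauss(gpe, stn, "bg_inhib")
    gauss(gpe, gpi, "bg_inhib")
    gauss(stn, gpe, "bg_excit")
    gauss(stn, gpi, "bg_excit")


def _wire_cerebellum(region, gauss):
    mf = f"{region}/pons:MF"
    gr = f"{region}/granular:granule"
    go = f"{region}/granular:golgi"
    pc = f"{region}/purkinje:PC"
    st = f"{region}/mol_upper:stellate"
    ba = f"{region}/mol_lower:basket"
    dcn = f"{region}/dcn:DCN"
    gauss(mf, gr, "mf_granule")
    gauss(mf, go, "mf_granule")
    gauss(mf, dcn, "mf_dcn")
    gauss(gr, go, "granule_golgi")
    gauss(go, gr, "golgi_granule")
    gauss(gr, pc, "pf_pc")
    gauss(gr, st, "pf_interneuron")
    gauss(gr, ba, "pf_interneuron")
    gauss(st, pc, "molecular_pc")
    gauss(ba, pc, "molecular_pc")
    gauss(pc, dcn, "pc_dcn")
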