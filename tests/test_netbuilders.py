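"""Network constructors: censuses, fixed indegree, placement, Gaussian
kernel statistics, CBCT structure and the drive calibration search."""

import numpy as np
import pytest

from embsnn import KernelConfig, Network, StaticSynapse
from embsnn.netbuilders import place_neurons_2d
from embsnn.netbuilders.brunel import (build_brunel, count_brunel,
                                       recurrent_indegrees)
from embsnn.netbuilders import cbct
from embsnn.netbuilders.calibrate import CalibrationError, calibrate_resting_input


# ---- balanced network ---------------------------------------------------


@pytest.mark.parametrize("scale,neurons", [(20, 225000), (1, 11250),
                                           (0.02, 225), (0.01, 112)])
def test_brunel_census_scaling(scale, neurons):
    n, nodes, conns = count_brunel(scale)
    assert n == neurons
    assert nodes == neurons + 1
    assert conns == neurons * 11250 + neurons


def test_brunel_census_rejects_nonpositive_scale():
    with pytest.raises(ValueError):
        count_brunel(0.0)


def test_brunel_budget_guard_names_the_census():
    with pytest.raises(ValueError, match="2,531,475,000"):
        build_brunel(20)


def test_brunel_instantiated_census_matches_dry_run():
    h = build_brunel(0.01, config=KernelConfig(seed=2))
    assert h.census == count_brunel(0.01)
    assert h.net.kernel_status()["num_neurons"] == 112


def test_brunel_every_neuron_has_indegree_11250():
    h = build_brunel(0.01, config=KernelConfig(seed=3), record=False)
    ind = recurrent_indegrees(h)
    assert len(ind) == 112
    assert (ind == 11250).all()


def test_brunel_smoke_simulation_completes():
    h = build_brunel(0.01, config=KernelConfig(seed=1))
    h.net.simulate(1000.0)
    ev = h.net.get_spikes(h.recorder)
    assert len(ev) >= 0
    assert h.net.time == pytest.approx(1000.0)


def test_brunel_ee_synapses_plastic_rest_static():
    h = build_brunel(0.01, config=KernelConfig(seed=1), record=False)
    projs = [p for w in h.net.workers for p in w.projections]
    stdp = [p for p in projs if p.stdp is not None]
    assert len(stdp) == 1
    assert stdp[0].pre is h.exc and stdp[0].post is h.exc


# ---- placement and Gaussian connectivity -------------------------------


def test_place_neurons_2d_contract():
    assert place_neurons_2d(0, 1.0, 1).shape == (0, 2)
    pts = place_neurons_2d(100_000, 2.0, 7)
    assert ((pts >= 0) & (pts <= 2.0)).all()
    # mean within 4 sigma of extent/2 per axis
    se = 2.0 / np.sqrt(12 * 100_000)
    assert np.abs(pts.mean(axis=0) - 1.0).max() < 4 * se
    with pytest.raises(ValueError):
        place_neurons_2d(10, -1.0, 1)


def test_gaussian_connection_probability_matches_kernel_in_4sigma_bands():
    n, p0, sigma = 2000, 0.6, 0.2
    net = Network(KernelConfig(seed=17))
    pos = place_neurons_2d(n, 1.0, 17, stream_key=1)
    sheet = net.create("lif_current", n, positions=pos)
    net.connect(sheet, sheet,
                {"rule": "pairwise_gaussian", "p0": p0, "sigma": sigma},
                StaticSynapse())
    (proj,) = [p for w in net.workers for p in w.projections]
    post_off = net.workers[0].pops[id(sheet)]["offsets"][proj.post_local]
    d_conn = np.linalg.norm(pos[proj.pre_idx] - pos[post_off], axis=1)

    # per bin: pair count and the exact expected hit probability (the
    # kernel averaged over the pairs that fall in the bin)
    edges = np.linspace(0.0, 0.8, 9)
    tot = np.zeros(len(edges) - 1)
    p_sum = np.zeros(len(edges) - 1)
    for i in range(n):
        d = np.linalg.norm(pos - pos[i], axis=1)
        d = np.delete(d, i)                       # no autapses
        tot += np.histogram(d, bins=edges)[0]
        p_sum += np.histogram(d, bins=edges,
                              weights=p0 * np.exp(-d**2 / (2 * sigma**2)))[0]
    hit = np.histogram(d_conn, bins=edges)[0]
    ok = tot > 500
    p_bar = p_sum[ok] / tot[ok]
    p_hat = hit[ok] / tot[ok]
    band = 4 * np.sqrt(p_bar * (1 - p_bar) / tot[ok])
    assert ok.sum() >= 6
    assert (np.abs(p_hat - p_bar) < band).all()


def test_topographic_pathways_preserve_spatial_order():
    net = Network(KernelConfig(seed=5))
    x_pre = np.linspace(0.05, 0.95, 40)
    x_post = np.linspace(0.0, 1.0, 60)
    pre = net.create("lif_current", 40,
                     positions=np.column_stack([x_pre, np.zeros(40)]))
    post = net.create("lif_current", 60,
                      positions=np.column_stack([x_post, np.zeros(60)]))
    cbct._topographic_connect(net, pre, post, p0=0.0, sigma=0.1,
                              weight=1.0, delay=1.0, receptor=None)
    (proj,) = [p for w in net.workers for p in w.projections if len(p.pre_idx)]
    order = np.argsort(proj.post_local)
    nearest = proj.pre_idx[order]
    assert (np.diff(nearest) >= 0).all()          # monotone in position
    assert len(nearest) == 60                     # every post reached


# ---- CBCT composition and build ----------------------------------------


def test_cbct_census_reproduces_published_totals():
    c = cbct.census_cbct(1.0)
    assert c["total_neurons"] == 1_005_905
    assert c["regions"] == {"M1": 58805, "S1": 94396, "VL": 6144, "VM": 6144,
                            "BG": 10976, "CB_M1": 414720, "CB_S1": 414720}
    assert c["n_layers"] == 33
    assert c["n_layers_from_rows"] == 33


def test_cbct_thalamic_zones_are_three_times_1024():
    c = cbct.census_cbct(1.0)
    for nucleus in ("VL", "VM"):
        for zone in ("zoneCB", "zoneBG"):
            for t in ("TC", "IN", "RT"):
                assert c["per_population"][f"{nucleus}/{zone}:{t}"] == 1024


def test_cortical_ei_ratio_is_4_to_1_outside_l1():
    comp = cbct.load_composition()
    by_layer = {}
    for row in comp["populations"]:
        if row["region"] not in ("M1", "S1") or row["layer"] == "L1":
            continue
        key = (row["region"], row["layer"])
        e, i = by_layer.get(key, (0, 0))
        if row["ei"] == "E":
            e += row["count"]
        else:
            i += row["count"]
        by_layer[key] = (e, i)
    assert by_layer
    for (region, layer), (e, i) in by_layer.items():
        assert e == 4 * i, f"{region}/{layer}: {e}:{i}"


def test_scaled_census_is_sum_of_rounded_parts():
    c1 = cbct.census_cbct(1.0)
    c = cbct.census_cbct(0.5)
    assert c["total_neurons"] == sum(
        round(v * 0.5) for v in c1["per_population"].values())
    with pytest.raises(ValueError):
        cbct.census_cbct(0.0)
    with pytest.raises(ValueError):
        cbct.census_cbct(1.5)


def test_cbct_build_census_matches_dry_run_and_has_all_pathways():
    h = cbct.build_cbct(0.01, config=KernelConfig(seed=1))
    assert h.n_neurons_built == cbct.census_cbct(0.01)["total_neurons"]
    assert set(h.pathways) == set(cbct.PATHWAY_NAMES)
    for name, n in h.pathways.items():
        assert n >= 1, f"pathway {name!r} has no connections"
    assert len(h.relays) > 0                      # parrot interfaces present
    # positions everywhere, one sheet extent
    for pop in h.pops.values():
        assert pop.positions is not None
        assert ((pop.positions >= 0) & (pop.positions <= 1.0)).all()


def test_cbct_m1_only_subset_builds_without_pathways():
    h = cbct.build_cbct(0.01, config=KernelConfig(seed=1), regions=("M1",))
    assert set(h.pathways) == set()
    assert h.n_neurons_built == cbct.census_cbct(0.01)["regions"]["M1"]


def test_cerebellum_resting_rate_near_calibration_point():
    """Short probe of the packaged calibrated drive (the acceptance run
    uses the full 5 s window)."""
    h = cbct.build_cerebellum(0.02, config=KernelConfig(seed=2))
    h.net.simulate(1500.0)
    r = h.rate("CB_M1/pons:MF", 500.0, 1500.0)
    assert r == pytest.approx(8.0, abs=1.5)


# ---- calibration search -------------------------------------------------


def test_calibration_converges_on_monotone_toy_response():
    # analytic f-I style curve: rate = drive / 50
    probe = lambda drive: drive / 50.0
    r = calibrate_resting_input(probe, target_rate_hz=8.0, tol_hz=0.1,
                                initial_rate=1000.0)
    assert r == pytest.approx(400.0, abs=0.1 * 50)


def test_calibration_returns_initial_rate_when_already_on_target():
    history = []

    def probe(drive):
        history.append(drive)
        return 8.0

    assert calibrate_resting_input(probe, 8.0, tol_hz=0.5,
                                   initial_rate=123.0) == 123.0
    assert history == [123.0]                     # zero search iterations


def test_zero_tolerance_is_a_documented_failure():
    with pytest.raises(CalibrationError, match="strictly positive"):
        calibrate_resting_input(lambda d: d, 8.0, tol_hz=0.0)


def test_unbracketable_target_fails_with_diagnostics():
    with pytest.raises(CalibrationError, match="bracket"):
        calibrate_resting_input(lambda d: 0.0, 8.0, tol_hz=0.1, max_iter=5)
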