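"""Master-worker control plane: combination heuristics, lifecycle, and the
API-transparency contract (n workers indistinguishable from one)."""

import numpy as np
import pytest

from embsnn.server import (CombinedResponse, DivergenceError, HTTPClient,
                           SimServer, combine, serve_http)


# ---- combine heuristics -------------------------------------------------


def test_identical_scalars_collapse():
    assert combine([{"time": 7.0}] * 3, "Simulate") == {"time": 7.0}


def test_additive_fields_are_summed():
    resp = combine([{"connections": 3}, {"connections": 5}], "Connect")
    assert resp == {"connections": 8}


def test_combining_is_associative_over_worker_order():
    parts = [{"connections": a} for a in (1, 2, 3, 4)]
    assert combine(parts, "Connect") == combine(parts[::-1], "Connect")


def test_contradictory_scalars_raise_divergence():
    with pytest.raises(DivergenceError, match="resolution"):
        combine([{"resolution": 0.1}, {"resolution": 0.2}], "GetKernelStatus")


def test_event_lists_merge_sorted_by_time_then_gid():
    parts = [
        {"events": {"gids": [3, 1], "times": [1.0, 2.0]}},
        {"events": {"gids": [2], "times": [1.0]}},
    ]
    out = combine(parts, "GetStatus")
    assert out["events"] == {"gids": [2, 3, 1], "times": [1.0, 1.0, 2.0]}


def test_unknown_endpoint_rejected():
    with pytest.raises(ValueError, match="endpoint"):
        combine([{}], "Frobnicate")


# ---- lifecycle ----------------------------------------------------------


def test_double_start_is_an_error_and_stop_resets():
    srv = SimServer(n_workers=2).start()
    with pytest.raises(RuntimeError, match="already started"):
        srv.start()
    srv.stop()
    srv.start()
    srv.stop()


def test_call_before_start_fails():
    srv = SimServer(1)
    with pytest.raises(RuntimeError, match="not started"):
        srv.call("GetKernelStatus")


# ---- API behaviour ------------------------------------------------------


def _script(srv: SimServer):
    srv.call("Create", {"model": "lif_current", "n": 10, "name": "n",
                        "params": {"I_e": 400.0}})
    srv.call("Create", {"model": "spike_recorder", "n": 1, "name": "rec"})
    srv.call("Connect", {"pre": "n", "post": "n",
                         "rule": {"rule": "fixed_indegree", "indegree": 3},
                         "syn": {"weight": 5.0, "delay": 1.0}})
    srv.call("Connect", {"pre": "n", "post": "rec"})
    srv.call("Simulate", {"duration": 200.0})
    return srv


def test_create_reports_one_population_split_over_workers():
    srv = SimServer(n_workers=2).start()
    resp = srv.call("Create", {"model": "lif_current", "n": 10, "name": "a"})
    assert resp.value["count"] == 10
    assert resp.value["local_count"] == 10        # summed over workers
    assert [p["local_count"] for p in resp.provenance] == [5, 5]


def test_serving_the_api_never_advances_the_clock():
    srv = SimServer(1).start()
    srv.call("Create", {"model": "lif_current", "n": 3, "name": "a"})
    assert srv.call("GetKernelStatus").value["time"] == 0.0
    srv.call("Simulate", {"duration": 100.0})
    assert srv.call("GetKernelStatus").value["time"] == 100.0


def test_worker_clocks_agree_after_simulate():
    srv = SimServer(n_workers=3).start()
    srv.call("Create", {"model": "lif_current", "n": 6, "name": "a"})
    resp = srv.call("Simulate", {"duration": 100.0})
    assert [p["time"] for p in resp.provenance] == [100.0] * 3


@pytest.mark.parametrize("n_workers", [2, 4])
def test_api_transparency_multiworker_equals_single(n_workers):
    """The acceptance oracle of the control plane: any script produces the
    same combined observable state for n workers as for one."""
    one = _script(SimServer(1).start())
    many = _script(SimServer(n_workers=n_workers).start())
    st1 = one.call("GetKernelStatus").value
    stn = many.call("GetKernelStatus").value
    # the additive local counters sum to the same global totals
    assert st1["local_num_neurons"] == stn["local_num_neurons"]
    assert st1["local_num_connections"] == stn["local_num_connections"]
    assert st1["time"] == stn["time"]
    ev1 = one.call("GetStatus", {"pop": "rec"}).value["events"]
    evn = many.call("GetStatus", {"pop": "rec"}).value["events"]
    assert ev1 == evn
    assert len(ev1["gids"]) > 0


def test_load_network_from_description():
    desc = {
        "kernel": {"resolution": 0.1, "seed": 9},
        "populations": [
            {"name": "a", "model": "lif_current", "count": 5,
             "params": {"I_e": 400.0}},
            {"name": "rec", "model": "spike_recorder", "count": 1},
        ],
        "connections": [{"pre": "a", "post": "rec"}],
    }
    srv = SimServer(1).start()
    resp = srv.call("LoadNetwork", {"description": desc})
    assert resp.value["populations"] == 2
    srv.call("Simulate", {"duration": 100.0})
    ev = srv.call("GetStatus", {"pop": "rec"}).value["events"]
    assert len(ev["gids"]) > 0


# ---- HTTP binding -------------------------------------------------------


def test_http_binding_round_trip():
    srv = SimServer(n_workers=2).start()
    httpd = serve_http(srv, port=0)       # ephemeral port
    port = httpd.server_address[1]
    try:
        client = HTTPClient(port=port)
        r = client.call("Create", {"model": "lif_current", "n": 4, "name": "a",
                                   "params": {"I_e": 400.0}})
        assert r.value["count"] == 4
        client.call("Create", {"model": "spike_recorder", "n": 1, "name": "rec"})
        client.call("Connect", {"pre": "a", "post": "rec"})
        client.call("Simulate", {"duration": 100.0})
        ev = client.call("GetStatus", {"pop": "rec"}).value["events"]
        direct = srv.net.get_spikes(srv._pops["rec"])
        assert ev["gids"] == direct["gid"].tolist()
        assert np.allclose(ev["times"], direct["t"])
        # errors surface as HTTP 400, not silent masking
        import urllib.error
        with pytest.raises(urllib.error.HTTPError):
            client.call("Nonsense", {})
    finally:
        httpd.shutdown()
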