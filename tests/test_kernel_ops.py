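"""Kernel operations: allocation, connection rules, relays, recorders,
round-robin distribution and the worker-count invariance contract."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from embsnn import (KernelConfig, LIFCurrentParams, Network, Population,
                    StaticSynapse, owner_worker)
from conftest import build_mixed_network


# ---- create -------------------------------------------------------------


def test_create_allocates_fresh_contiguous_ids():
    net = Network(KernelConfig())
    a = net.create("lif_current", 5)
    assert (a.first_id, a.count) == (1, 5)
    b = net.create("parrot", 1)
    c = net.create("lif_current", 20)
    ids = np.concatenate([a.gids, b.gids, c.gids])
    assert len(np.unique(ids)) == 26
    assert ids.max() == 26


def test_create_rejects_unknown_model_and_bad_params():
    net = Network(KernelConfig())
    with pytest.raises(ValueError, match="unknown model"):
        net.create("izhikevich", 1)
    with pytest.raises(ValueError):
        net.create("lif_current", 0)
    with pytest.raises(ValueError):
        net.create("lif_current", 1, {"tau_m": -1.0})
    with pytest.raises(ValueError):   # V_reset >= V_th
        net.create("lif_current", 1, {"V_reset": -50.0, "V_th": -55.0})


def test_neurons_initialize_at_resting_potential():
    net = Network(KernelConfig())
    pop = net.create("lif_current", 4, LIFCurrentParams(E_L=-65.0))
    assert np.allclose(net.get_voltages(pop)[1], -65.0)


# ---- connect ------------------------------------------------------------


def test_one_to_one_requires_equal_sizes_and_counts_exactly():
    net = Network(KernelConfig())
    a = net.create("lif_current", 4)
    b = net.create("lif_current", 4)
    c = net.create("lif_current", 5)
    assert net.connect(a, b, "one_to_one") == 4
    with pytest.raises(ValueError, match="equal"):
        net.connect(a, c, "one_to_one")


def test_all_to_all_excludes_autapses_on_self_connection():
    net = Network(KernelConfig())
    a = net.create("lif_current", 10)
    assert net.connect(a, a, "all_to_all") == 10 * 9


@pytest.mark.parametrize("n_pre,n_post,k", [(5, 7, 12), (50, 20, 7), (3, 3, 100)])
def test_fixed_indegree_gives_exactly_k_per_post(n_pre, n_post, k):
    net = Network(KernelConfig(seed=5))
    pre = net.create("lif_current", n_pre)
    post = net.create("lif_current", n_post)
    n = net.connect(pre, post, {"rule": "fixed_indegree", "indegree": k})
    assert n == n_post * k
    counts = np.zeros(n_post, dtype=int)
    for w in net.workers:
        for proj in w.projections:
            np.add.at(counts, w.pops[id(post)]["offsets"][proj.post_local], 1)
    assert (counts == k).all()


def test_gaussian_kernel_degenerates_to_all_to_all_and_to_empty():
    net = Network(KernelConfig(seed=2))
    pos = np.random.default_rng(0).uniform(0, 1, (10, 2))
    a = net.create("lif_current", 10, positions=pos)
    b = net.create("lif_current", 10, positions=pos + 0.01)
    syn = StaticSynapse()
    full = net.connect(a, b, {"rule": "pairwise_gaussian", "p0": 1.0, "sigma": 1e9}, syn)
    assert full == 100
    assert net.connect(a, b, {"rule": "pairwise_gaussian", "p0": 0.0, "sigma": 0.1},
                       syn) == 0


def test_gaussian_requires_positions():
    net = Network(KernelConfig())
    a = net.create("lif_current", 3)
    b = net.create("lif_current", 3)
    with pytest.raises(ValueError, match="positions"):
        net.connect(a, b, {"rule": "pairwise_gaussian", "p0": 0.5, "sigma": 0.1})


def test_delay_below_min_delay_is_rejected():
    net = Network(KernelConfig(min_delay=1.0))
    a = net.create("lif_current", 2)
    with pytest.raises(ValueError, match="min_delay"):
        net.connect(a, a, "all_to_all", StaticSynapse(delay=0.5))


def test_simulate_rejects_offgrid_duration():
    net = Network(KernelConfig())
    net.create("lif_current", 1)
    with pytest.raises(ValueError):
        net.simulate(10.05)
    with pytest.raises(ValueError):
        net.simulate(-1.0)
    net.simulate(20.0)
    assert net.step == 200 and net.time == pytest.approx(20.0)


# ---- distribution -------------------------------------------------------


def test_owner_worker_round_robin():
    assert owner_worker(5, 4) == 1
    assert all(owner_worker(g, 1) == 0 for g in range(50))
    owners = np.array([owner_worker(g, 4) for g in range(100)])
    assert (np.bincount(owners) == 25).all()


@given(n_workers=st.integers(1, 8), n=st.integers(1, 200))
def test_round_robin_partitions_every_gid_exactly_once(n_workers, n):
    owners = [owner_worker(g, n_workers) for g in range(n)]
    assert all(0 <= o < n_workers for o in owners)
    assert sum(np.bincount(owners, minlength=n_workers)) == n


def test_population_state_is_sharded_by_gid_modulo_workers():
    net = Network(KernelConfig(n_workers=3))
    pop = net.create("lif_current", 10)
    for w in net.workers:
        gids = w.pops[id(pop)]["gids"]
        assert (gids % 3 == w.worker_id).all()
    total = sum(len(w.pops[id(pop)]["gids"]) for w in net.workers)
    assert total == 10


# ---- relays, devices, recorders ----------------------------------------


def test_parrot_relays_input_spike_shifted_by_delay():
    net = Network(KernelConfig(seed=1))
    gen = net.create("spike_generator", 1, {"spike_times": [5.0]})
    par = net.create("parrot", 1)
    rec = net.create("spike_recorder", 1)
    net.connect(gen, par, "one_to_one", StaticSynapse(delay=1.0))
    net.connect(par, rec)
    net.simulate(10.0)
    ev = net.get_spikes(rec)
    assert len(ev) == 1
    assert ev["t"][0] == pytest.approx(6.0)
    assert ev["gid"][0] == par.first_id


def test_parrot_relays_full_train_exactly():
    times = [1.0, 2.5, 2.6, 7.0, 9.9]
    net = Network(KernelConfig(seed=1))
    gen = net.create("spike_generator", 1, {"spike_times": times})
    par = net.create("parrot", 1)
    rec = net.create("spike_recorder", 1)
    net.connect(gen, par, "one_to_one", StaticSynapse(delay=2.0))
    net.connect(par, rec)
    net.simulate(15.0)
    assert np.allclose(net.get_spikes(rec)["t"], np.array(times) + 2.0)


def test_poisson_generator_long_run_count():
    net = Network(KernelConfig(seed=7))
    gen = net.create("poisson_generator", 1, {"rate": 1000.0})
    par = net.create("parrot", 1)
    rec = net.create("spike_recorder", 1)
    net.connect(gen, par, syn=StaticSynapse(delay=1.0))
    net.connect(par, rec)
    net.simulate(10_000.0)
    n = len(net.get_spikes(rec))
    assert abs(n - 10_000) < 4 * np.sqrt(10_000)


def test_get_spikes_empty_window_and_inverted_window():
    net = Network(KernelConfig())
    net.create("lif_current", 2)
    rec = net.create("spike_recorder", 1)
    net.simulate(10.0)
    assert len(net.get_spikes(rec)) == 0
    with pytest.raises(ValueError, match="inverted"):
        net.get_spikes(rec, 5.0, 1.0)


def test_spike_events_sorted_by_time_then_gid():
    net, rec = build_mixed_network(1)
    net.simulate(300.0)
    ev = net.get_spikes(rec)
    assert len(ev) > 0
    key = ev["t"] * 10**7 + ev["gid"]
    assert (np.diff(key) > 0).all() or (np.diff(ev["t"]) >= 0).all()


# ---- the module's central invariant ------------------------------------


@pytest.mark.parametrize("n_workers", [2, 4])
def test_spike_output_is_bitwise_invariant_to_worker_count(n_workers):
    net1, rec1 = build_mixed_network(1)
    net1.simulate(400.0)
    ref = net1.get_spikes(rec1)
    netn, recn = build_mixed_network(n_workers)
    netn.simulate(400.0)
    assert len(ref) > 10, "network must be active for the check to bite"
    assert np.array_equal(ref, netn.get_spikes(recn))


def test_repeated_runs_are_bitwise_deterministic():
    a = build_mixed_network(1)
    a[0].simulate(300.0)
    b = build_mixed_network(1)
    b[0].simulate(300.0)
    assert np.array_equal(a[0].get_spikes(a[1]), b[0].get_spikes(b[1]))
    va = a[0].get_voltages(a[0].populations[0])[1]
    vb = b[0].get_voltages(b[0].populations[0])[1]
    assert np.array_equal(va, vb)


def test_membrane_state_is_also_worker_invariant():
    net1, _ = build_mixed_network(1)
    net1.simulate(200.0)
    net4, _ = build_mixed_network(4)
    net4.simulate(200.0)
    for pop1, pop4 in zip(net1.populations[:2], net4.populations[:2]):
        assert np.array_equal(net1.get_voltages(pop1)[1],
                              net4.get_voltages(pop4)[1])
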