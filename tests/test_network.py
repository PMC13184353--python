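"""Symptom networks: Spearman weights, modularity, Louvain, restart census."""

import numpy as np
import pandas as pd
import pytest

import apathynet as an
from apathynet.network import (
    Partition,
    apriori_partition,
    louvain_once,
    modularity,
    sparse_edges,
    stable_partition,
    summarise_modules,
)

from conftest import (
    exhaustive_max_modularity,
    random_connected_network,
    toy_network,
    two_triangles,
)


def _dataset_from_columns(cols: dict, domains: dict):
    from apathynet.scales import CohortDataset, ScaleDefinition

    items = tuple(cols)
    n = len(next(iter(cols.values())))
    ids = [f"p{i}" for i in range(n)]
    scale = ScaleDefinition("custom", items, domains)
    resp = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()}, index=ids)
    return CohortDataset(
        participant_ids=ids,
        cohort=np.array(["HC"] * n, dtype=object),
        age=np.full(n, 40.0),
        mode=np.array(["unknown"] * n, dtype=object),
        responses=resp,
        missing_mask=pd.DataFrame(False, index=ids, columns=list(items)),
        scale=scale,
    )


def test_identical_and_reversed_items_have_unit_weight():
    x = [0, 1, 2, 3, 4, 0, 2, 4, 1, 3]
    ds = _dataset_from_columns(
        {"a": x, "b": x, "c": [4 - v for v in x]},
        {"a": "Behavioural", "b": "Behavioural", "c": "Social"},
    )
    net = an.spearman_network(ds)
    assert net.W[0, 1] == pytest.approx(1.0)
    assert net.signed_R[0, 2] == pytest.approx(-1.0)
    assert net.W[0, 2] == pytest.approx(1.0)  # absolute value


def test_constant_item_edges_zeroed_with_warning():
    ds = _dataset_from_columns(
        {"a": [0, 1, 2, 3, 4], "b": [2, 2, 2, 2, 2], "c": [4, 3, 2, 1, 0]},
        {"a": "Behavioural", "b": "Behavioural", "c": "Social"},
    )
    with pytest.warns(UserWarning, match="zero rank variance"):
        net = an.spearman_network(ds)
    assert np.all(net.W[1, :] == 0.0)


def test_planted_blocks_have_higher_within_than_between_weight(cohort3_4000, ami_scale):
    net = an.spearman_network(cohort3_4000)
    doms = np.array([ami_scale.domain_of[i] for i in net.items])
    same = doms[:, None] == doms[None, :]
    off = ~np.eye(18, dtype=bool)
    assert net.W[same & off].mean() > net.W[~same].mean()


def test_modularity_known_values():
    tri = two_triangles()
    assert modularity(tri, Partition.from_labels([0] * 6)) == pytest.approx(0.0, abs=1e-12)
    assert modularity(tri, Partition.from_labels([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)
    # singleton partition: Q = -sum k_i^2 / (2m)^2
    rng = np.random.default_rng(5)
    net = random_connected_network(rng, 6)
    k = net.W.sum(axis=0)
    two_m = net.W.sum()
    q_ref = -float(np.sum(k**2) / two_m**2)
    assert modularity(net, Partition.from_labels(range(6))) == pytest.approx(q_ref, abs=1e-12)
    assert q_ref < 0


def test_louvain_recovers_components_and_merges_complete_graph():
    tri = two_triangles()
    part = louvain_once(tri, seed=0)
    assert part.labels == (0, 0, 0, 1, 1, 1)
    assert modularity(tri, part) == pytest.approx(0.5)
    full = toy_network(np.ones((6, 6)) - np.eye(6))
    part_full = louvain_once(full, seed=0)
    assert part_full.n_communities == 1  # Q = 0 is the maximum for a clique


def test_louvain_deterministic_given_seed():
    rng = np.random.default_rng(9)
    net = random_connected_network(rng, 8)
    assert louvain_once(net, seed=123) == louvain_once(net, seed=123)


def test_louvain_matches_exhaustive_oracle_on_small_graphs():
    rng = np.random.default_rng(17)
    for trial in range(6):
        net = random_connected_network(rng, int(rng.integers(5, 9)))
        q_max, _ = exhaustive_max_modularity(net)
        census = stable_partition(net, n_restarts=40, seed=trial)
        q_louvain = modularity(net, census.modal)
        assert q_louvain <= q_max + 1e-12
        assert q_louvain >= 0.95 * q_max - 1e-12


def test_stable_partition_shares():
    tri = two_triangles()
    census = stable_partition(tri, n_restarts=100, seed=1)
    assert census.modal_share == 1.0
    assert sum(census.counts.values()) == 100
    single = stable_partition(tri, n_restarts=1, seed=2)
    assert single.modal_share == 1.0


def test_permutation_equivariance():
    rng = np.random.default_rng(23)
    net = random_connected_network(rng, 8)
    perm = rng.permutation(8)
    W_p = net.W[np.ix_(perm, perm)]
    net_p = toy_network(W_p)
    part = stable_partition(net, n_restarts=60, seed=3).modal
    part_p = stable_partition(net_p, n_restarts=60, seed=3).modal
    # map the permuted partition back to original item order and canonicalise
    back = np.empty(8, dtype=int)
    back[perm] = np.asarray(part_p.labels)
    assert Partition.from_labels(back) == Partition.from_labels(part.labels)


def test_modal_beats_apriori_partition(cohort3_4000):
    net = an.spearman_network(cohort3_4000)
    census = stable_partition(net, n_restarts=100, seed=4)
    assert modularity(net, census.modal) >= modularity(net, apriori_partition(net)) - 1e-12


def test_planted_partition_share_nondecreasing_in_loading(ami_scale):
    shares = []
    for lam in (0.4, 0.55, 0.7):
        per_seed = []
        for seed in (101, 102, 103):
            spec = an.scale_factor_spec(ami_scale, within_load=lam, between_corr=0.3)
            ds = an.simulate_cohort(an.CohortSimSpec(n=4000, model=spec, seed=seed))
            net = an.spearman_network(ds)
            census = stable_partition(net, n_restarts=100, seed=seed)
            planted = apriori_partition(net)
            per_seed.append(census.counts.get(planted.labels, 0) / census.n_restarts)
        shares.append(np.mean(per_seed))
    assert shares[0] <= shares[1] + 1e-12 <= shares[2] + 2e-12


def test_module_summaries_purity_and_central_node():
    # module of 4 Social + 2 Behavioural items, fully connected with one
    # dominant node
    W = np.full((6, 6), 0.3)
    np.fill_diagonal(W, 0.0)
    W[0, 1] = W[1, 0] = 0.9  # node 0 and 1 strongest
    W[0, 2] = W[2, 0] = 0.9
    doms = ["Social", "Social", "Social", "Social", "Behavioural", "Behavioural"]
    net = toy_network(W, doms)
    mods = summarise_modules(net, Partition.from_labels([0] * 6))
    assert len(mods) == 1
    assert mods[0].modal_domain == "Social"
    assert mods[0].purity == pytest.approx(4 / 6)
    assert mods[0].central_node == "N0"
    singleton = summarise_modules(net, Partition.from_labels([0, 1, 2, 3, 4, 5]))
    assert all(m.purity == 1.0 and m.central_node == m.members[0] for m in singleton)


def test_between_domain_connectivity_toy():
    W = np.zeros((6, 6))
    doms = ["Behavioural", "Behavioural", "Social", "Social", "Emotional", "Emotional"]
    for i in range(6):
        for j in range(6):
            if i != j and doms[i] != doms[j]:
                W[i, j] = 0.2
    net = toy_network(W, doms)
    bdc = an.between_domain_connectivity(net)
    assert np.allclose(bdc.to_numpy(), 0.2)
    net_zero = toy_network(np.zeros((6, 6)), doms)
    assert np.allclose(an.between_domain_connectivity(net_zero).to_numpy(), 0.0)


def test_sparse_edges_threshold_inclusive_and_signed():
    W = np.array([[0.0, 0.05, 0.1], [0.05, 0.0, 0.3], [0.1, 0.3, 0.0]])
    signed = np.array([[1.0, 0.05, 0.1], [0.05, 1.0, -0.3], [0.1, -0.3, 1.0]])
    net = toy_network(W)
    net.signed_R = signed
    edges = sparse_edges(net, threshold=0.1)
    pairs = set(zip(edges["source"], edges["target"]))
    assert ("N0", "N2") in pairs  # boundary |rho| = 0.1 retained
    assert ("N0", "N1") not in pairs
    neg = edges[(edges["source"] == "N1") & (edges["target"] == "N2")]
    assert neg["sign"].iloc[0] == "negative"
    all_weak = toy_network(np.full((3, 3), 0.05) - 0.05 * np.eye(3))
    assert sparse_edges(all_weak, threshold=0.1).empty


def test_graphml_round_trip(tmp_path, cohort3_4000):
    import networkx as nx

    net = an.spearman_network(cohort3_4000)
    census = stable_partition(net, n_restarts=20, seed=6)
    path = tmp_path / "net.graphml"
    an.network.to_graphml(net, path, census.modal)
    g = nx.read_graphml(path)
    assert set(g.nodes) == set(net.items)
    node = g.nodes["AMI-1"]
    assert node["domain"] == "Emotional"
    assert "module" in node and "between_domain_connectivity" in node
    assert all(d["weight"] >= 0.1 for _, _, d in g.edges(data=True))
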