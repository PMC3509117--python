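import numpy as np
import pytest

from ystrpop import (
    build_median_joining_network, build_minimum_spanning_network,
    extract_founder_clusters, mp_prune, network_tables, rho_statistic,
)

from _oracles import minimum_spanning_structures


def edges_of(net):
    return {tuple(sorted(e)) for e in net.graph.edges()}


def test_msn_two_haplotypes():
    net = build_minimum_spanning_network([(0, 0), (2, 1)])
    assert edges_of(net) == {((0, 0), (2, 1))}
    assert net.graph.edges[(0, 0), (2, 1)]["steps"] == 3
    assert net.graph.edges[(0, 0), (2, 1)]["length"] == 30.0  # uniform weight 10


def test_msn_equidistant_triangle_kept():
    haps = [(0, 0), (1, 1), (0, 2)]  # pairwise step distance 2
    net = build_minimum_spanning_network(haps)
    assert len(edges_of(net)) == 3  # every edge lies in some MST


def test_msn_collinear_chain():
    net = build_minimum_spanning_network([(0, 0), (1, 0), (2, 0)])
    assert edges_of(net) == {((0, 0), (1, 0)), ((1, 0), (2, 0))}


def test_mj_quasi_median_already_observed_star():
    net = build_median_joining_network([(0, 0), (1, 0), (0, 1)])
    assert net.medians == []
    assert edges_of(net) == {((0, 0), (1, 0)), ((0, 0), (0, 1))}


def test_mj_chain_through_observed_intermediate():
    net = build_median_joining_network([(0, 0), (1, 1), (1, 0)])
    assert net.medians == []
    assert edges_of(net) == {((0, 0), (1, 0)), ((1, 0), (1, 1))}


def test_mj_adds_useful_median():
    # three haplotypes whose quasi-median (1,1) shortens the connection
    net = build_median_joining_network([(0, 0), (2, 1), (1, 2)])
    assert net.medians == [(1, 1)]
    assert edges_of(net) == {((0, 0), (1, 1)), ((1, 1), (2, 1)), ((1, 1), (1, 2))}


def test_mj_equals_msn_when_all_medians_observed():
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]  # closed under per-locus medians
    mj = build_median_joining_network(haps)
    msn = build_minimum_spanning_network(haps)
    assert edges_of(mj) == edges_of(msn)
    assert mj.medians == []


def test_mj_epsilon_validation_and_iteration_guard():
    with pytest.raises(ValueError):
        build_median_joining_network([(0, 0), (1, 1)], epsilon=-1)
    with pytest.raises(RuntimeError):
        build_median_joining_network([(0, 0), (5, 1), (1, 5), (6, 6)], max_iter=0)


def test_mp_prune_tree_unchanged():
    net = build_median_joining_network([(0, 0), (1, 0), (2, 0)])
    pruned = mp_prune(net)
    assert edges_of(pruned) == edges_of(net)


def test_mp_prune_triangle_unchanged():
    net = build_minimum_spanning_network([(0, 0), (1, 1), (0, 2)])
    pruned = mp_prune(net)
    assert edges_of(pruned) == edges_of(net)  # each edge is in some shortest tree


def test_mp_prune_removes_median_matching_exhaustive_search():
    haps = [(0, 1, 3), (1, 3, 2), (2, 0, 3), (2, 2, 3), (2, 3, 0)]
    net = build_median_joining_network(haps)
    assert (1, 2, 3) in net.medians
    pruned = mp_prune(net)
    assert (1, 2, 3) not in pruned.medians
    best, kept_edges, kept_nodes = minimum_spanning_structures(net.graph, haps)
    assert edges_of(pruned) == {tuple(sorted(e)) for e in kept_edges}
    assert set(pruned.graph.nodes) == kept_nodes | set(haps)


@pytest.mark.parametrize("seed", range(25))
def test_mp_prune_matches_exhaustive_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    haps = {tuple(int(x) for x in rng.integers(0, 4, 3))
            for _ in range(int(rng.integers(3, 7)))}
    haps = sorted(haps)
    if len(haps) < 2:
        haps = [(0, 0, 0), (1, 1, 1)]
    net = build_median_joining_network(haps)
    pruned = mp_prune(net)
    best, kept_edges, _ = minimum_spanning_structures(net.graph, haps)
    assert edges_of(pruned) == {tuple(sorted(e)) for e in kept_edges}
    # observed haplotypes all survive, network stays connected
    assert set(haps) <= set(pruned.graph.nodes)
    import networkx as nx

    assert nx.is_connected(pruned.graph)


def test_path_length_at_least_direct_distance():
    import networkx as nx

    rng = np.random.default_rng(42)
    haps = sorted({tuple(int(x) for x in rng.integers(0, 5, 3)) for _ in range(8)})
    net = build_median_joining_network(haps)
    for u in haps:
        for v in haps:
            if u >= v:
                continue
            path = nx.dijkstra_path_length(net.graph, u, v, weight="length")
            direct = 10 * sum(abs(a - b) for a, b in zip(u, v))
            assert path >= direct - 1e-9


def test_founder_clusters_single_shared_root(make_pop):
    focal = make_pop([(10, 10)] * 5, name="roma")
    source = make_pop([(10, 10), (12, 11)], name="nwi")
    net = build_median_joining_network([focal, source])
    clusters = extract_founder_clusters(net, ["roma"], ["nwi"])
    assert len(clusters) == 1
    assert clusters[0].root == (10, 10) and clusters[0].n == 5
    rho, sd = rho_statistic(clusters[0])
    assert rho == 0.0 and sd == 0.0


def test_founder_clusters_two_clumps(make_pop):
    focal = make_pop([(1, 0)] * 3 + [(11, 0)] * 2, name="roma")
    source = make_pop([(0, 0), (10, 0)], name="nwi")
    net = build_median_joining_network([focal, source])
    clusters = extract_founder_clusters(net, ["roma"], ["nwi"])
    roots = {c.root: c for c in clusters}
    assert set(roots) == {(1, 0), (11, 0)}  # source-adjacent focal nodes
    assert roots[(1, 0)].n == 3 and roots[(11, 0)].n == 2


def test_founder_clusters_manual_assignment(make_pop):
    focal = make_pop([(1, 0), (2, 0)], name="roma")
    source = make_pop([(0, 0)], name="nwi")
    net = build_median_joining_network([focal, source])
    assignment = {(1, 0): (0, 0), (2, 0): (0, 0)}
    clusters = extract_founder_clusters(net, ["roma"], ["nwi"], assignment=assignment)
    assert len(clusters) == 1 and clusters[0].root == (0, 0) and clusters[0].n == 2


def test_founder_clusters_missing_focal_label_errors(make_pop):
    source = make_pop([(0, 0)], name="nwi")
    net = build_median_joining_network([source])
    with pytest.raises(ValueError):
        extract_founder_clusters(net, ["roma"], ["nwi"])


def test_network_tables_and_export(tmp_path, make_pop):
    pop = make_pop([(0, 0), (2, 1), (1, 2)], name="p")
    net = build_median_joining_network([pop])
    nodes, edges = network_tables(net)
    assert nodes["median_vector"].sum() == 1
    assert (nodes["multiplicity"] >= 0).all()
    from ystrpop import write_network

    files = write_network(net, tmp_path / "net")
    assert all(f.exists() for f in files)
    gml = (tmp_path / "net.gml").read_text()
    assert "haplotype" in gml
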