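"""Independent brute-force oracles used by the test suite.

Everything here is written from definitions (explicit loops, exhaustive
enumeration) and deliberately shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import itertools


def allele_diff(a, b):
    return sum(1 for x, y in zip(a, b) if x != y)


def step_diff(a, b):
    return sum(abs(x - y) for x, y in zip(a, b))


def squared_diff(a, b):
    return sum((x - y) ** 2 for x, y in zip(a, b))


ORACLE_METRICS = {"allele": allele_diff, "step": step_diff, "squared": squared_diff}


def mpd_loop(individuals, metric="allele"):
    """MPD by the definitional double loop over individuals."""
    f = ORACLE_METRICS[metric]
    n = len(individuals)
    total = sum(f(individuals[i], individuals[j])
                for i in range(n) for j in range(i + 1, n))
    return total / (n * (n - 1) / 2)


def amova_two_level(pops, metric="allele"):
    """Two-level AMOVA (among/within populations) from first principles.

    ``pops`` is a list of lists of repeat tuples.  Returns
    (sigma_among, sigma_within, phi_st).
    """
    f = ORACLE_METRICS[metric]
    individuals = [(pi, h) for pi, pop in enumerate(pops) for h in pop]
    N = len(individuals)
    P = len(pops)
    sizes = [len(p) for p in pops]

    ss_total = sum(f(a, b) for (_, a), (_, b) in itertools.combinations(individuals, 2)) / N
    ss_w = sum(
        sum(f(a, b) for a, b in itertools.combinations(pop, 2)) / len(pop)
        for pop in pops
    )
    ss_a = ss_total - ss_w
    ms_a = ss_a / (P - 1)
    ms_w = ss_w / (N - P)
    n_coef = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - sigma_w) / n_coef
    tot = sigma_a + sigma_w
    return sigma_a, sigma_w, (sigma_a / tot if tot > 0 else 0.0)


def amova_nested(groups, metric="allele"):
    """Three-level AMOVA from first principles.

    ``groups`` is a list of groups, each a list of populations, each a list
    of repeat tuples.  Returns (sigma_a, sigma_b, sigma_c, phi_st, phi_sc,
    phi_ct).
    """
    f = ORACLE_METRICS[metric]
    pops = [pop for grp in groups for pop in grp]
    sizes = [len(p) for p in pops]
    N = sum(sizes)
    P = len(pops)
    G = len(groups)
    everyone = [h for p in pops for h in p]

    ss_total = sum(f(a, b) for a, b in itertools.combinations(everyone, 2)) / N
    ss_wp = sum(
        sum(f(a, b) for a, b in itertools.combinations(pop, 2)) / len(pop)
        for pop in pops
    )
    ss_wg = 0.0
    for grp in groups:
        members = [h for p in grp for h in p]
        ss_wg += sum(f(a, b) for a, b in itertools.combinations(members, 2)) / len(members)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    ms_ag = ss_ag / (G - 1)
    ms_ap = ss_ap / (P - G)
    ms_wp = ss_wp / (N - P)

    Ng = [sum(len(p) for p in grp) for grp in groups]
    sum_np2_over_Ng = sum(
        sum(len(p) ** 2 for p in grp) / ng for grp, ng in zip(groups, Ng))
    n1 = (N - sum_np2_over_Ng) / (P - G)
    n2 = (sum_np2_over_Ng - sum(s * s for s in sizes) / N) / (G - 1)
    n3 = (N - sum(ng * ng for ng in Ng) / N) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / tot if tot > 0 else 0.0
    phi_ct = sigma_a / tot if tot > 0 else 0.0
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
    return sigma_a, sigma_b, sigma_c, phi_st, phi_sc, phi_ct


def minimum_spanning_structures(graph, observed):
    """Exhaustively enumerate minimum-length trees spanning the observed nodes.

    ``graph`` is a networkx graph with edge attribute ``length``; any
    non-observed node may be used or skipped.  Returns (best_length,
    set_of_edges_in_some_minimal_tree, set_of_nodes_in_some_minimal_tree).
    """
    edges = [(min(u, v), max(u, v), d["length"]) for u, v, d in graph.edges(data=True)]
    observed = set(observed)
    best = None
    kept_edges: set = set()
    kept_nodes: set = set()
    for r in range(len(observed) - 1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            nodes = set()
            for u, v, _ in subset:
                nodes.update((u, v))
            if not observed <= (nodes or observed):
                continue
            if observed - nodes and len(observed) > 1:
                continue
            if len(subset) != len(nodes) - 1:
                continue  # a tree has exactly |V|-1 edges
            # connectivity by BFS
            adj = {}
            for u, v, _ in subset:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)
            start = next(iter(nodes))
            seen = {start}
            stack = [start]
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if seen != nodes:
                continue
            weight = sum(w for _, _, w in subset)
            if best is None or weight < best - 1e-9:
                best = weight
                kept_edges = {(u, v) for u, v, _ in subset}
                kept_nodes = set(nodes)
            elif abs(weight - best) <= 1e-9:
                kept_edges |= {(u, v) for u, v, _ in subset}
                kept_nodes |= nodes
    return best, kept_edges, kept_nodes
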