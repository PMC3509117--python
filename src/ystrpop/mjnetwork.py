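"""Median-joining haplotype networks for multistate STR data.

The pipeline follows the classic construction for ordered multistate
characters: a minimum spanning network (the union of all minimum spanning
trees under the weighted step metric, optionally relaxed by a tolerance
``epsilon``), iterative addition of quasi-medians (per-locus medians of
connected node triplets) while they lower connection cost, and a final
maximum-parsimony pruning that deletes median vectors and links absent from
every minimum-length tree connecting the observed haplotypes.

Founder-cluster extraction partitions "focal" (e.g. diaspora) haplotypes
around root nodes shared with, or adjacent to, "source" haplotypes — the
input to ρ/TD founder dating.

Nodes are plain tuples of repeat counts; per-node population multiplicities
live in node attributes.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .strdata import Dataset, PopulationSample, STRHaplotype

__all__ = [
    "HaplotypeNetwork",
    "FounderCluster",
    "build_minimum_spanning_network",
    "build_median_joining_network",
    "mp_prune",
    "extract_founder_clusters",
    "network_tables",
    "write_network",
]


@dataclass
class HaplotypeNetwork:
    """A haplotype network over observed nodes and inferred median vectors."""

    graph: nx.Graph
    epsilon: float = 0.0
    weights: tuple[float, ...] | None = None

    @property
    def observed(self) -> list[tuple]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("observed"))

    @property
    def medians(self) -> list[tuple]:
        return sorted(n for n, d in self.graph.nodes(data=True) if not d.get("observed"))

    def node_multiplicity(self, node, labels=None) -> int:
        pops = self.graph.nodes[node].get("pops", Counter())
        if labels is None:
            return sum(pops.values())
        return sum(c for p, c in pops.items() if p in labels)


@dataclass
class FounderCluster:
    """A founder root plus the focal haplotypes assigned to it."""

    root: tuple
    members: Counter = field(default_factory=Counter)

    @property
    def n(self) -> int:
        return sum(self.members.values())


# ---------------------------------------------------------------------------
# input collection and distances

def _collect(haps) -> dict:
    """Normalise input to {repeat-tuple: Counter(population -> count)}."""
    table: dict[tuple, Counter] = {}

    def add(hap, pop, count=1):
        t = tuple(getattr(hap, "repeats", hap))
        table.setdefault(t, Counter())[pop] += count

    if isinstance(haps, Dataset):
        pops = haps.populations
    elif isinstance(haps, PopulationSample):
        pops = [haps]
    elif isinstance(haps, (list, tuple)) and haps and isinstance(haps[0], PopulationSample):
        pops = haps
    else:
        for h in haps:
            add(h, "sample")
        pops = []
    for p in pops:
        for h, c in p.haplotypes.items():
            add(h, p.name, c)
    if not table:
        raise ValueError("no haplotypes supplied")
    lengths = {len(t) for t in table}
    if len(lengths) > 1:
        raise ValueError(f"haplotypes mix panel sizes {sorted(lengths)}")
    return table


def _wdist(a: tuple, b: tuple, w: np.ndarray) -> float:
    return float(np.dot(w, np.abs(np.asarray(a) - np.asarray(b))))


def _weight_vector(L: int, weights) -> np.ndarray:
    if weights is None:
        return np.full(L, 10.0)  # conventional uniform character weight
    w = np.asarray(weights, dtype=float)
    if w.shape != (L,):
        raise ValueError(f"weights must have one entry per locus ({L})")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return w


# ---------------------------------------------------------------------------
# minimum spanning network

class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _dist_matrix(mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.einsum("l,ijl->ij", w, np.abs(mat[:, None, :] - mat[None, :, :]))


def _msn_edge_indices(D: np.ndarray, epsilon: float) -> list[tuple[int, int]]:
    """Index pairs of the epsilon-relaxed union of minimum spanning trees.

    An edge (u, v) at distance d is retained iff u and v lie in different
    components of the graph formed by all node pairs at distance < d -
    epsilon (epsilon = 0 gives exactly the union-of-all-MSTs criterion).
    """
    m = D.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    weights = D[iu, ju]
    order = np.argsort(weights, kind="stable")
    iu, ju, weights = iu[order], ju[order], weights[order]

    edges: list[tuple[int, int]] = []
    if epsilon == 0:
        # single Kruskal-style pass: within each equal-weight tier, test all
        # edges against the components formed by strictly shorter edges,
        # then merge the whole tier
        dsu = _DSU(m)
        start = 0
        npairs = weights.shape[0]
        while start < npairs:
            stop = start
            wlevel = weights[start]
            while stop < npairs and weights[stop] == wlevel:
                stop += 1
            tier = [(int(iu[k]), int(ju[k])) for k in range(start, stop)]
            edges.extend((a, b) for a, b in tier if dsu.find(a) != dsu.find(b))
            for a, b in tier:
                dsu.union(a, b)
            start = stop
    else:
        levels = np.unique(weights)
        for level in levels:
            dsu = _DSU(m)
            below = weights < level - epsilon
            for a, b in zip(iu[below], ju[below]):
                dsu.union(int(a), int(b))
            at = weights == level
            edges.extend(
                (int(a), int(b)) for a, b in zip(iu[at], ju[at])
                if dsu.find(int(a)) != dsu.find(int(b))
            )
    return edges


def _msn_edges(nodes: list[tuple], w: np.ndarray, epsilon: float) -> list[tuple]:
    """MSN edges as (node, node, weighted distance) triples."""
    mat = np.asarray(nodes, dtype=np.int64)
    D = _dist_matrix(mat, w)
    return [(nodes[a], nodes[b], float(D[a, b]))
            for a, b in _msn_edge_indices(D, epsilon)]


def build_minimum_spanning_network(haps, weights=None, epsilon: float = 0.0) -> HaplotypeNetwork:
    """Union of all minimum spanning trees over the weighted step metric.

    With ``epsilon > 0`` additional near-minimal links within the tolerance
    are retained, as in the conventional relaxation.
    """
    table = _collect(haps)
    nodes = sorted(table)
    L = len(nodes[0])
    w = _weight_vector(L, weights)
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, observed=True, pops=table[n])
    for u, v, d in _msn_edges(nodes, w, epsilon):
        steps = int(np.abs(np.asarray(u) - np.asarray(v)).sum())
        g.add_edge(u, v, length=d, steps=steps)
    return HaplotypeNetwork(g, epsilon=epsilon, weights=tuple(w))


# ---------------------------------------------------------------------------
# median joining

def _quasi_median(u: tuple, v: tuple, x: tuple) -> tuple:
    return tuple(int(np.median([a, b, c])) for a, b, c in zip(u, v, x))


def build_median_joining_network(haps, epsilon: float = 0.0, weights=None,
                                 max_iter: int = 50) -> HaplotypeNetwork:
    """Median-joining network: MSN plus cost-reducing quasi-median vectors.

    Each round builds the MSN over the current node set, visits every
    connected triplet (two of its three links present), and adds the
    per-locus median of the triplet when it is a new vector whose star
    connection is cheaper than linking the triplet pairwise.  Terminates
    when no new medians arise; ``max_iter`` guards against non-termination.
    """
    table = _collect(haps)
    observed = sorted(table)
    L = len(observed[0])
    w = _weight_vector(L, weights)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    nodes = sorted(set(observed))
    it = 0
    while True:
        mat = np.asarray(nodes, dtype=np.int64)
        D = _dist_matrix(mat, w)
        edge_idx = _msn_edge_indices(D, epsilon)
        adj: dict[int, list] = {i: [] for i in range(len(nodes))}
        for a, b in edge_idx:
            adj[a].append(b)
            adj[b].append(a)
        node_set = set(nodes)
        new = set()
        for x in range(len(nodes)):
            for a, b in itertools.combinations(sorted(adj[x]), 2):
                trip = np.sort(mat[[a, b, x], :], axis=0)
                m = tuple(int(r) for r in trip[1])  # per-locus median
                if m in node_set or m in new:
                    continue
                dab, dax, dbx = D[a, b], D[a, x], D[b, x]
                pairwise_cost = dab + dax + dbx - max(dab, dax, dbx)
                marr = np.asarray(m, dtype=np.int64)
                star_cost = sum(
                    float(np.dot(w, np.abs(mat[i] - marr))) for i in (a, b, x))
                if star_cost < pairwise_cost:
                    new.add(m)
        if not new:
            break
        it += 1
        if it > max_iter:
            raise RuntimeError(
                f"median joining did not converge in {max_iter} iterations "
                f"({len(nodes) - len(observed)} median vectors so far)"
            )
        nodes = sorted(node_set | new)

    g = nx.Graph()
    for n in sorted(nodes):
        g.add_node(n, observed=n in table, pops=table.get(n, Counter()))
    for u, v, d in _msn_edges(sorted(nodes), w, epsilon):
        steps = int(np.abs(np.asarray(u) - np.asarray(v)).sum())
        g.add_edge(u, v, length=d, steps=steps)

    # drop median vectors that end up as leaves: they lie in no shortest
    # connection of observed nodes
    while True:
        dead = [n for n, d in g.nodes(data=True)
                if not d["observed"] and g.degree(n) <= 1]
        if not dead:
            break
        g.remove_nodes_from(dead)
    return HaplotypeNetwork(g, epsilon=epsilon, weights=tuple(w))


# ---------------------------------------------------------------------------
# maximum parsimony pruning

def mp_prune(network: HaplotypeNetwork, max_medians: int = 16,
             on_overflow: str = "error") -> HaplotypeNetwork:
    """Keep only links/medians lying in some minimum-length spanning tree.

    Considers every subset of median vectors, finds the minimum total length
    of a tree spanning all observed haplotypes (medians optional), and
    retains exactly the edges contained in at least one such minimal tree.
    Observed nodes are never deleted.  The search is exponential in the
    number of medians; beyond ``max_medians`` it either raises or (with
    ``on_overflow="skip"``) returns the network unchanged.
    """
    g = network.graph
    observed = network.observed
    medians = network.medians
    if len(medians) > max_medians:
        if on_overflow == "skip":
            return network
        raise RuntimeError(
            f"MP pruning over {len(medians)} median vectors exceeds the "
            f"exhaustive-search cap ({max_medians})"
        )

    best = None
    optimal_subsets = []
    for r in range(len(medians) + 1):
        for subset in itertools.combinations(medians, r):
            nodes = set(observed) | set(subset)
            sub = g.subgraph(nodes)
            if sub.number_of_nodes() != len(nodes) or not nx.is_connected(sub):
                continue
            weight = sum(d["length"] for _, _, d in
                         nx.minimum_spanning_edges(sub, weight="length", data=True))
            if best is None or weight < best - 1e-9:
                best = weight
                optimal_subsets = [subset]
            elif abs(weight - best) <= 1e-9:
                optimal_subsets.append(subset)
    if best is None:
        raise RuntimeError("observed haplotypes are not connected in the network")

    kept_edges = set()
    kept_nodes = set(observed)
    for subset in optimal_subsets:
        nodes = set(observed) | set(subset)
        sub = g.subgraph(nodes)
        for u, v, d in sub.edges(data=True):
            # cut rule: an edge lies in some MST iff its endpoints are
            # disconnected using only strictly shorter edges
            shorter = [(a, b) for a, b, dd in sub.edges(data=True)
                       if dd["length"] < d["length"] - 1e-12]
            test = nx.Graph(shorter)
            test.add_nodes_from(nodes)
            if not nx.has_path(test, u, v):
                kept_edges.add((min(u, v), max(u, v)))
                kept_nodes.update((u, v))

    pruned = nx.Graph()
    for n in kept_nodes:
        pruned.add_node(n, **g.nodes[n])
    for u, v in kept_edges:
        pruned.add_edge(u, v, **g.edges[u, v])
    if not nx.is_connected(pruned):
        raise RuntimeError("internal error: MP pruning disconnected the network")
    return HaplotypeNetwork(pruned, epsilon=network.epsilon, weights=network.weights)


# ---------------------------------------------------------------------------
# founder clusters

def extract_founder_clusters(network: HaplotypeNetwork, focal_labels, source_labels,
                             assignment: dict | None = None) -> list[FounderCluster]:
    """Partition focal haplotypes into founder clusters.

    Roots are network nodes carrying both focal and source population labels
    (shared haplotypes); if none exist, focal nodes adjacent to a
    source-carrying node serve as roots.  Each focal node is assigned to the
    root reachable by the shortest network path passing through no other
    root (ties to the lexicographically smallest root).  A user-supplied
    ``assignment`` (focal node -> root node) overrides the automatic rule,
    allowing published clusterings to be reproduced exactly.
    """
    g = network.graph
    focal = set(focal_labels)
    source = set(source_labels)

    def mult(node, labels):
        return network.node_multiplicity(node, labels)

    focal_nodes = [n for n in g.nodes if mult(n, focal) > 0]
    if not focal_nodes:
        raise ValueError(f"no nodes carry focal labels {sorted(focal)}")

    if assignment is not None:
        clusters: dict[tuple, FounderCluster] = {}
        for node in focal_nodes:
            root = tuple(getattr(assignment[node], "repeats", assignment[node]))
            clusters.setdefault(root, FounderCluster(root)).members[node] += mult(node, focal)
        return [clusters[r] for r in sorted(clusters)]

    roots = sorted(n for n in g.nodes if mult(n, focal) > 0 and mult(n, source) > 0)
    if not roots:
        roots = sorted(
            n for n in focal_nodes
            if any(mult(nb, source) > 0 for nb in g.neighbors(n))
        )
    if not roots:
        raise ValueError("no candidate founder roots (no shared or source-adjacent focal nodes)")

    # shortest path from each root avoiding the other roots
    dist_from_root: dict[tuple, dict] = {}
    for r in roots:
        keep = set(g.nodes) - (set(roots) - {r})
        dist_from_root[r] = nx.single_source_dijkstra_path_length(
            g.subgraph(keep), r, weight="length")

    clusters = {r: FounderCluster(r) for r in roots}
    for node in sorted(focal_nodes):
        cands = [(dist_from_root[r].get(node), r) for r in roots
                 if node in dist_from_root[r]]
        if not cands:  # every path passes another root; fall back to plain distance
            cands = [(nx.dijkstra_path_length(g, r, node, weight="length"), r)
                     for r in roots]
        d, root = min(cands, key=lambda c: (c[0], c[1]))
        clusters[root].members[node] += mult(node, focal)
    return [clusters[r] for r in roots if clusters[r].n > 0]


# ---------------------------------------------------------------------------
# export

def network_tables(network: HaplotypeNetwork):
    """Node and edge tables (pandas DataFrames) for export/visualisation."""
    import pandas as pd

    g = network.graph
    ids = {n: f"N{i:03d}" for i, n in enumerate(sorted(g.nodes))}
    node_rows = []
    for n in sorted(g.nodes):
        d = g.nodes[n]
        pops = d.get("pops", Counter())
        node_rows.append({
            "id": ids[n],
            "haplotype": ",".join(map(str, n)),
            "median_vector": not d.get("observed", False),
            "multiplicity": sum(pops.values()),
            "populations": ";".join(f"{p}:{c}" for p, c in sorted(pops.items())),
        })
    edge_rows = []
    for u, v, d in sorted(g.edges(data=True)):
        diffs = np.abs(np.asarray(u) - np.asarray(v))
        edge_rows.append({
            "source": ids[u], "target": ids[v],
            "length": d["length"], "steps": d["steps"],
            "locus_diffs": ",".join(map(str, diffs)),
        })
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)


def write_network(network: HaplotypeNetwork, basename, formats=("tsv", "gml", "dot")) -> list:
    """Write the network as edge-list TSV, GML and/or DOT files."""
    from pathlib import Path

    basename = Path(basename)
    nodes, edges = network_tables(network)
    written = []
    if "tsv" in formats:
        np_, ep = basename.with_suffix(".nodes.tsv"), basename.with_suffix(".edges.tsv")
        nodes.to_csv(np_, sep="\t", index=False)
        edges.to_csv(ep, sep="\t", index=False)
        written += [np_, ep]
    if "gml" in formats:
        ids = dict(zip(nodes["id"], nodes.index))
        h = nx.Graph()
        for _, row in nodes.iterrows():
            h.add_node(row["id"], haplotype=row["haplotype"],
                       median=int(row["median_vector"]),
                       multiplicity=int(row["multiplicity"]),
                       populations=row["populations"])
        for _, row in edges.iterrows():
            h.add_edge(row["source"], row["target"],
                       length=float(row["length"]), steps=int(row["steps"]))
        p = basename.with_suffix(".gml")
        nx.write_gml(h, p)
        written.append(p)
    if "dot" in formats:
        p = basename.with_suffix(".dot")
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("graph haplotype_network {\n")
            for _, row in nodes.iterrows():
                shape = "point" if row["median_vector"] else "circle"
                fh.write(f'  {row["id"]} [label="{row["haplotype"]}" shape={shape} '
                         f'width={0.2 + 0.1 * row["multiplicity"]:.2f}];\n')
            for _, row in edges.iterrows():
                fh.write(f'  {row["source"]} -- {row["target"]} '
                         f'[label="{row["steps"]}"];\n')
            fh.write("}\n")
        written.append(p)
    return written
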