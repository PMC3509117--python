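"""Between-population distances, AMOVA and multidimensional scaling.

The between-population toolkit of Y-STR phylogeography:

* mean pairwise differences within (PiX) and between (PiXY) populations;
* Goldstein's (δμ)² distance — mean over loci of the squared difference in
  mean repeat count, linear in divergence time under the stepwise mutation
  model;
* distance-based Analysis of Molecular Variance (Excoffier-Quattro-Smouse)
  with two-level (populations) and three-level (groups of populations)
  designs, yielding Φ statistics;
* pairwise Rst (Slatkin) as the two-population Φ_ST under the squared-step
  metric, and haplotypic Φ_ST matrices under the allele metric;
* classical (Torgerson) metric MDS with reported eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import cross_distance_matrix, distance_matrix
from .strdata import Dataset, PopulationSample

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "MDSResult",
    "pi_within",
    "pi_between",
    "delta_mu_squared",
    "amova",
    "amova_permutation_test",
    "pairwise_phi_st",
    "rst_matrix",
    "delta_mu_matrix",
    "combined_distance_table",
    "mds_embed",
]


@dataclass
class DistanceMatrix:
    """A symmetric labelled population distance matrix."""

    labels: list[str]
    values: np.ndarray
    measure: str
    raw: np.ndarray | None = None  # unclamped estimates, where clamping applies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab[:10].ljust(10) + " " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pairwise mean differences and (δμ)²

def pi_within(pop: PopulationSample, metric: str = "allele") -> float:
    """Mean pairwise distance within a population (PiX); requires n >= 2."""
    if pop.n < 2:
        raise ValueError(f"population {pop.name!r}: PiX undefined for n < 2")
    mat, counts = pop.to_arrays()
    d = distance_matrix(mat, metric)
    return 0.5 * float(counts @ d @ counts) / (pop.n * (pop.n - 1) / 2)


def pi_between(popA: PopulationSample, popB: PopulationSample, metric: str = "allele") -> float:
    """Mean distance over all nA x nB cross-population pairs (PiXY)."""
    mA, cA = popA.to_arrays()
    mB, cB = popB.to_arrays()
    d = cross_distance_matrix(mA, mB, metric)
    return float(cA @ d @ cB) / (popA.n * popB.n)


def delta_mu_squared(popA: PopulationSample, popB: PopulationSample) -> float:
    """Goldstein's (δμ)²: mean over loci of (mean repeats A - mean repeats B)²."""
    mA, cA = popA.to_arrays()
    mB, cB = popB.to_arrays()
    if mA.shape[1] != mB.shape[1]:
        raise ValueError("panel size mismatch between populations")
    muA = (cA @ mA) / popA.n
    muB = (cB @ mB) / popB.n
    return float(np.mean((muA - muB) ** 2))


# ---------------------------------------------------------------------------
# AMOVA

@dataclass
class AmovaResult:
    """Variance components and Φ statistics of a distance-based AMOVA.

    ``sigma`` holds the raw (possibly negative) components keyed
    ``among_groups`` / ``among_populations`` / ``within_populations``;
    Φ statistics are computed from the raw components.
    """

    sigma: dict
    ss: dict
    df: dict
    phi_st: float
    phi_sc: float | None = None
    phi_ct: float | None = None
    n_permutations: int = 0
    p_value: float | None = None

    @property
    def sigma_clamped(self) -> dict:
        return {k: max(v, 0.0) for k, v in self.sigma.items()}


def _pair_sum(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared distances over unordered pairs within index set."""
    sub = d2[np.ix_(idx, idx)]
    return 0.5 * float(sub.sum())


def amova(dataset: Dataset, grouping: dict | None = None, metric: str = "allele",
          d2: np.ndarray | None = None) -> AmovaResult:
    """Distance-based AMOVA over a dataset.

    With ``grouping`` (population name → group label, >= 2 groups) the full
    three-level nested design is fitted (among groups / among populations
    within groups / within populations).  Without it, the two-level design
    (among populations / within populations) is fitted and ``phi_st`` is the
    ordinary fixation index.

    The metric value of a pair of individuals is used directly as the
    squared distance entering the sums of squares (the haplotypic-data
    convention); use ``metric="squared"`` for Rst-type analyses.
    """
    pops = dataset.populations
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    sizes = np.array([p.n for p in pops])
    N = int(sizes.sum())
    P = len(pops)
    if N - P < 1:
        raise ValueError("within-population component undefined: no population has n > 1")

    if d2 is None:
        X = np.vstack([p.expand() for p in pops])
        d2 = distance_matrix(X, metric)
    pop_idx = np.repeat(np.arange(P), sizes)

    all_idx = np.arange(N)
    ss_total = _pair_sum(d2, all_idx) / N
    ss_wp = sum(_pair_sum(d2, np.flatnonzero(pop_idx == p)) / sizes[p] for p in range(P))

    if grouping is None:
        ss_ap = ss_total - ss_wp
        df_ap, df_wp = P - 1, N - P
        ms_ap, ms_wp = ss_ap / df_ap, ss_wp / df_wp
        sigma_c = ms_wp
        n_coef = (N - float(np.sum(sizes ** 2)) / N) / (P - 1)
        sigma_a = (ms_ap - sigma_c) / n_coef
        tot = sigma_a + sigma_c
        phi_st = sigma_a / tot if tot > 0 else 0.0
        return AmovaResult(
            sigma={"among_populations": sigma_a, "within_populations": sigma_c},
            ss={"among_populations": ss_ap, "within_populations": ss_wp, "total": ss_total},
            df={"among_populations": df_ap, "within_populations": df_wp},
            phi_st=phi_st,
        )

    groups = sorted(set(grouping.values()))
    G = len(groups)
    if G < 2:
        raise ValueError("grouping must define at least two groups")
    group_of_pop = np.array([groups.index(grouping[p.name]) for p in pops])
    grp_idx = group_of_pop[pop_idx]
    Ng = np.array([sizes[group_of_pop == g].sum() for g in range(G)], dtype=float)

    ss_within_groups = sum(
        _pair_sum(d2, np.flatnonzero(grp_idx == g)) / Ng[g] for g in range(G)
    )
    ss_ag = ss_total - ss_within_groups
    ss_ap = ss_within_groups - ss_wp

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    if df_ap < 1:
        raise ValueError("need more populations than groups for the nested design")
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp

    sum_np2_by_group = np.array([np.sum(sizes[group_of_pop == g] ** 2) for g in range(G)], dtype=float)
    n1 = (N - float(np.sum(sum_np2_by_group / Ng))) / (P - G)
    n2 = (float(np.sum(sum_np2_by_group / Ng)) - float(np.sum(sizes ** 2)) / N) / (G - 1)
    n3 = (N - float(np.sum(Ng ** 2)) / N) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / tot if tot > 0 else 0.0
    phi_ct = sigma_a / tot if tot > 0 else 0.0
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
    return AmovaResult(
        sigma={"among_groups": sigma_a, "among_populations": sigma_b,
               "within_populations": sigma_c},
        ss={"among_groups": ss_ag, "among_populations": ss_ap,
            "within_populations": ss_wp, "total": ss_total},
        df={"among_groups": df_ag, "among_populations": df_ap, "within_populations": df_wp},
        phi_st=phi_st, phi_sc=phi_sc, phi_ct=phi_ct,
    )


def amova_permutation_test(dataset: Dataset, metric: str = "allele",
                           n_permutations: int = 999, seed: int = 0) -> AmovaResult:
    """Two-level AMOVA with a label-permutation p-value for Φ_ST.

    Individuals are permuted among populations; the p-value is the fraction
    of permuted Φ_ST values >= the observed one (observed included).
    """
    rng = np.random.default_rng(seed)
    pops = dataset.populations
    sizes = [p.n for p in pops]
    X = np.vstack([p.expand() for p in pops])
    d2 = distance_matrix(X, metric)
    obs = amova(dataset, metric=metric, d2=d2)

    N = X.shape[0]
    count = 1
    for _ in range(n_permutations):
        perm = rng.permutation(N)
        d2p = d2[np.ix_(perm, perm)]
        r = amova(dataset, metric=metric, d2=d2p)
        if r.phi_st >= obs.phi_st - 1e-12:
            count += 1
    obs.n_permutations = n_permutations
    obs.p_value = count / (n_permutations + 1)
    return obs


def pairwise_phi_st(dataset: Dataset, metric: str = "allele", clamp: bool = True) -> DistanceMatrix:
    """Matrix of pairwise two-population Φ_ST values under the given metric."""
    pops = dataset.populations
    P = len(pops)
    if P < 2:
        raise ValueError("need at least two populations")
    raw = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            sub = Dataset(dataset.panel, [pops[i], pops[j]])
            raw[i, j] = raw[j, i] = amova(sub, metric=metric).phi_st
    vals = np.maximum(raw, 0.0) if clamp else raw.copy()
    measure = "Rst" if metric == "squared" else "Fst"
    return DistanceMatrix([p.name for p in pops], vals, measure, raw=raw)


def rst_matrix(dataset: Dataset, clamp: bool = True) -> DistanceMatrix:
    """Pairwise Rst (Slatkin): two-population Φ_ST with squared-step distances."""
    return pairwise_phi_st(dataset, metric="squared", clamp=clamp)


def delta_mu_matrix(dataset: Dataset) -> DistanceMatrix:
    pops = dataset.populations
    P = len(pops)
    vals = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            vals[i, j] = vals[j, i] = delta_mu_squared(pops[i], pops[j])
    return DistanceMatrix([p.name for p in pops], vals, "(dmu)2")


def combined_distance_table(dataset: Dataset, metric: str = "allele") -> pd.DataFrame:
    """Combined report matrix: PiX on the diagonal, PiXY above it, (δμ)² below."""
    pops = dataset.populations
    labels = [p.name for p in pops]
    P = len(pops)
    out = np.zeros((P, P))
    for i in range(P):
        out[i, i] = pi_within(pops[i], metric)
        for j in range(i + 1, P):
            out[i, j] = pi_between(pops[i], pops[j], metric)
            out[j, i] = delta_mu_squared(pops[i], pops[j])
    return pd.DataFrame(out, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# classical MDS

@dataclass
class MDSResult:
    """Classical-MDS coordinates plus the full eigenvalue spectrum.

    Negative eigenvalues flag departures from Euclidean embeddability
    (e.g. triangle-inequality violations); their mass is visible to callers.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    labels: list[str] = field(default_factory=list)


def mds_embed(matrix, dims: int = 2) -> MDSResult:
    """Classical (Torgerson) metric MDS of a symmetric distance matrix."""
    if isinstance(matrix, DistanceMatrix):
        labels, D = matrix.labels, matrix.values
    else:
        D = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(dims, n)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    if k < dims:
        coords = np.hstack([coords, np.zeros((n, dims - k))])
    return MDSResult(coords=coords, eigenvalues=evals, labels=list(labels))
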