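"""Within-population Y-STR diversity statistics.

Implements the summary statistics conventionally reported for Y-STR
haplotype samples: haplotype diversity (HD) with Nei's sampling SD, mean
pairwise difference (MPD) with a Tajima-style total SD, mean per-locus
repeat-number variance, the modal haplotype, and the average mutational
distance (AMD) from a reference haplotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import cross_distance_matrix, distance_matrix, pair_distance
from .strdata import PopulationSample, STRHaplotype

__all__ = [
    "DiversitySummary",
    "haplotype_diversity",
    "mean_pairwise_difference",
    "repeat_variance",
    "modal_haplotype",
    "avg_mutational_distance",
    "diversity_summary",
]


@dataclass(frozen=True)
class DiversitySummary:
    """One population's row of a diversity report."""

    name: str
    n: int
    h: int
    hd: float
    hd_sd: float
    mpd: float
    mpd_sd: float
    variance: float
    amd: float | None = None


def _require_n2(pop: PopulationSample) -> None:
    if pop.n < 2:
        raise ValueError(f"population {pop.name!r}: estimator undefined for n < 2")


def haplotype_diversity(pop: PopulationSample) -> tuple[float, float]:
    """Haplotype diversity HD = n/(n-1) (1 - Σ p_i²) and its sampling SD.

    The SD is the square root of Nei's (1987) variance of gene diversity,

        V = 2/(n(n-1)) { 2(n-2) [Σp³ - (Σp²)²] + Σp² - (Σp²)² },

    the estimator behind the ± column of standard haplotype-diversity
    software output.
    """
    _require_n2(pop)
    n = pop.n
    _, counts = pop.to_arrays()
    p = counts / n
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return hd, math.sqrt(max(var, 0.0))


def mean_pairwise_difference(pop: PopulationSample, metric: str = "allele") -> tuple[float, float]:
    """Mean pairwise distance over all unordered pairs of individuals.

    Pairs of individuals sharing a haplotype contribute 0.  The SD is the
    square root of Tajima's total (sampling + stochastic) variance

        V = b1 π + b2 π²,  b1 = (n+1)/(3(n-1)),  b2 = 2(n²+n+3)/(9n(n-1)).
    """
    _require_n2(pop)
    n = pop.n
    mat, counts = pop.to_arrays()
    d = distance_matrix(mat, metric)
    # sum over unordered individual pairs = 1/2 * c^T d c  (diagonal of d is 0)
    total = 0.5 * float(counts @ d @ counts)
    mpd = total / (n * (n - 1) / 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    return mpd, math.sqrt(b1 * mpd + b2 * mpd * mpd)


def repeat_variance(pop: PopulationSample) -> float:
    """Mean over loci of the sample variance (n-1 denominator) of repeat counts."""
    _require_n2(pop)
    X = pop.expand()
    return float(np.mean(np.var(X, axis=0, ddof=1)))


def modal_haplotype(pop: PopulationSample, per_locus: bool = False) -> STRHaplotype:
    """The most frequent haplotype; ties go to the lexicographically smallest.

    ``per_locus=True`` instead returns the vector of per-locus modal alleles
    (smallest allele on a per-locus tie), which need not be an observed
    haplotype.
    """
    if pop.n < 1:
        raise ValueError("empty population")
    if per_locus:
        X = pop.expand()
        modes = []
        for col in X.T:
            vals, cnts = np.unique(col, return_counts=True)
            modes.append(int(vals[np.argmax(cnts)]))  # np.unique sorts: tie -> smallest
        return STRHaplotype(tuple(modes))
    best = max(pop.haplotypes.values())
    return min(h for h, c in pop.haplotypes.items() if c == best)


def avg_mutational_distance(pop: PopulationSample, ref: STRHaplotype,
                            metric: str = "allele") -> float:
    """Mean distance of the population's individuals from a reference haplotype."""
    if len(ref) != len(next(iter(pop.haplotypes))):
        raise ValueError("reference haplotype is not on the population's panel")
    mat, counts = pop.to_arrays()
    d = cross_distance_matrix(mat, np.asarray(ref.repeats)[None, :], metric)[:, 0]
    return float(d @ counts) / pop.n


def diversity_summary(pop: PopulationSample, ref: STRHaplotype | None = None,
                      metric: str = "allele") -> DiversitySummary:
    """Bundle the per-population statistics into one record."""
    hd, hd_sd = haplotype_diversity(pop)
    mpd, mpd_sd = mean_pairwise_difference(pop, metric)
    var = repeat_variance(pop)
    amd = avg_mutational_distance(pop, ref, metric) if ref is not None else None
    return DiversitySummary(pop.name, pop.n, pop.h, hd, hd_sd, mpd, mpd_sd, var, amd)
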