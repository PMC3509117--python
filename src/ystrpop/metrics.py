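"""Pairwise haplotype metrics.

Three metrics are used throughout:

``allele``
    Number of loci at which two haplotypes carry different alleles (the
    "number of different alleles" distance of haplotypic analyses).
``step``
    Total number of single-repeat mutational steps: sum over loci of
    |Δ repeats|.  Used for network branch lengths and ρ dating.
``squared``
    Sum over loci of (Δ repeats)²; the squared-step distance underlying
    Rst-type statistics and ASD/TD dating.

All three are symmetric and non-negative; ``allele`` and ``step`` are zero
iff the haplotypes are equal (``squared`` too, being a sum of squares).
"""

from __future__ import annotations

import numpy as np

__all__ = ["METRICS", "pair_distance", "distance_matrix", "cross_distance_matrix"]

METRICS = ("allele", "step", "squared")


def _apply(diff: np.ndarray, metric: str) -> np.ndarray:
    if metric == "allele":
        return (diff != 0).sum(axis=-1)
    if metric == "step":
        return np.abs(diff).sum(axis=-1)
    if metric == "squared":
        return (diff ** 2).sum(axis=-1)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def pair_distance(a, b, metric: str = "allele") -> float:
    """Distance between two repeat vectors under the chosen metric."""
    a = np.asarray(getattr(a, "repeats", a), dtype=np.int64)
    b = np.asarray(getattr(b, "repeats", b), dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError(f"haplotype length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(_apply(a - b, metric))


def distance_matrix(A: np.ndarray, metric: str = "allele") -> np.ndarray:
    """All-pairs distances among the rows of an ``n x L`` repeat matrix."""
    A = np.asarray(A, dtype=np.int64)
    return _apply(A[:, None, :] - A[None, :, :], metric).astype(float)


def cross_distance_matrix(A: np.ndarray, B: np.ndarray, metric: str = "allele") -> np.ndarray:
    """Distances between rows of A (``nA x L``) and rows of B (``nB x L``)."""
    A = np.asarray(A, dtype=np.int64)
    B = np.asarray(B, dtype=np.int64)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"panel size mismatch: {A.shape[1]} vs {B.shape[1]}")
    return _apply(A[:, None, :] - B[None, :, :], metric).astype(float)
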