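"""Closeness and consistency objective for matrix refinement.

A refined matrix should stay close to the expert's original judgments while
becoming consistent.  Closeness is measured by the discrepancy index DI, a
reciprocal-ratio distance over the lower-triangle entries g (original) and g'
(candidate):

    DI = [ sum_k ( g'_k/g_k + g_k/g'_k ) ] / (n^2 - n)  -  1

Each term x + 1/x is at least 2 by AM-GM, so DI >= 0 with equality exactly
when the two matrices agree.  Reciprocity makes the upper-triangle terms
identical to the lower ones, so only the n(n-1)/2 lower entries are summed
and the (n^2 - n) denominator absorbs the doubled count.

Consistency is measured by the eigenvalue gap lambda_max - n, and the two are
combined additively into the objective index OI = DI + (lambda_max - n) that
the optimizers minimize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import PairwiseComparisonMatrix, lambda_max

__all__ = [
    "TriangleVector",
    "ObjectiveValue",
    "lower_triangle",
    "discrepancy_index",
    "objective_index",
]


@dataclass(frozen=True)
class TriangleVector:
    """Lower-triangle entries of a reciprocal matrix, row-major, length n(n-1)/2."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != self.n * (self.n - 1) // 2:
            raise ValueError("triangle length must be n(n-1)/2")
        if np.any(v <= 0):
            raise ValueError("triangle values must be positive")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ObjectiveValue:
    di: float
    lambda_gap: float
    oi: float


def lower_triangle(M: PairwiseComparisonMatrix) -> TriangleVector:
    """Strictly-lower-triangle entries in row-major order (a21, a31, a32, ...)."""
    i, j = np.tril_indices(M.n, k=-1)
    return TriangleVector(values=M.entries[i, j], n=M.n)


def _check_compatible(a: PairwiseComparisonMatrix, b: PairwiseComparisonMatrix):
    if a.n != b.n:
        raise ValueError(f"matrix orders differ: {a.n} vs {b.n}")
    if a.labels != b.labels:
        raise ValueError(f"matrix labels differ: {a.labels} vs {b.labels}")


def discrepancy_index(
    candidate: PairwiseComparisonMatrix, original: PairwiseComparisonMatrix
) -> float:
    """DI between a candidate matrix and the original judgments (0 iff equal)."""
    _check_compatible(candidate, original)
    g = lower_triangle(original).values
    gp = lower_triangle(candidate).values
    n = original.n
    ratio = gp / g
    di = float(np.sum(ratio + 1.0 / ratio) / (n * n - n) - 1.0)
    # each summand is >= 2, the mean over n^2-n slots is >= 1; clip fp dust
    return max(di, 0.0)


def objective_index(
    candidate: PairwiseComparisonMatrix,
    original: PairwiseComparisonMatrix,
    lambda_method: str = "mean_ratio",
) -> ObjectiveValue:
    """OI = DI(candidate, original) + (lambda_max(candidate) - n), gap floored at 0."""
    di = discrepancy_index(candidate, original)
    gap = lambda_max(candidate, method=lambda_method) - candidate.n
    gap = max(gap, 0.0)  # guard against -1e-12 artifacts on consistent matrices
    return ObjectiveValue(di=di, lambda_gap=gap, oi=di + gap)
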