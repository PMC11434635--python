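"""Pairwise-comparison matrices and eigenvalue-based consistency measures.

The Analytic Hierarchy Process (AHP) derives criterion priorities from a
positive reciprocal matrix A = (a_ij), where a_ij states how many times more
important criterion i is than criterion j on the Saaty 1-9 scale.  This module
holds the matrix container, the two standard weight-extraction procedures
(column normalization with row averaging, and the principal eigenvector), and
the consistency diagnostics lambda_max, CI, RI and CR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SAATY_VALUES",
    "PairwiseComparisonMatrix",
    "WeightVector",
    "ConsistencyReport",
    "ScoreMatrix",
    "RankedOptions",
    "validate_matrix",
    "compute_weights",
    "lambda_max",
    "random_index",
    "consistency",
    "rank_options",
    "consistent_from_weights",
]

#: Admissible judgment values: 1..9 and their reciprocals (17 values).
SAATY_VALUES: np.ndarray = np.sort(
    np.concatenate([1.0 / np.arange(2.0, 10.0), [1.0], np.arange(2.0, 10.0)])
)

#: Saaty's Random Index: expected CI of random reciprocal matrices of order n.
RANDOM_INDEX = {
    3: 0.58, 4: 0.9, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Judgments with CR at or below this threshold are accepted as consistent.
CR_THRESHOLD = 0.1

_RECIPROCITY_RTOL = 1e-9


class MatrixValidationError(ValueError):
    """Raised when a raw grid fails pairwise-comparison-matrix validation."""


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """A validated n-by-n positive reciprocal judgment matrix with labels."""

    entries: np.ndarray
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))

    def permuted(self, perm: list[int]) -> "PairwiseComparisonMatrix":
        """Simultaneous row/column relabeling; consistency is invariant to it."""
        p = np.asarray(perm)
        return PairwiseComparisonMatrix(
            self.entries[np.ix_(p, p)], tuple(self.labels[i] for i in perm)
        )


@dataclass(frozen=True)
class WeightVector:
    """Normalized criterion priorities (non-negative, summing to one)."""

    weights: np.ndarray
    method: str = "column_norm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ConsistencyReport:
    """lambda_max, CI, RI, CR and the verdict for one judgment matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "cr_rounded": round(self.cr, 3),
            "consistent": self.consistent,
        }


@dataclass(frozen=True)
class ScoreMatrix:
    """Option-by-criterion scores; each criterion column sums to one."""

    scores: np.ndarray
    option_labels: tuple[str, ...]
    criterion_labels: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.scores.shape[0]

    @property
    def n(self) -> int:
        return self.scores.shape[1]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("score grid must be two-dimensional")
        if np.any(s < 0):
            raise ValueError("scores must be non-negative")
        col = s.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-9):
            raise ValueError("each criterion column must sum to 1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "option_labels", tuple(self.option_labels))
        object.__setattr__(self, "criterion_labels", tuple(self.criterion_labels))


@dataclass(frozen=True)
class RankedOptions:
    """Final option values v = P w and the descending ranking order."""

    values: np.ndarray
    order: tuple[int, ...]
    option_labels: tuple[str, ...] = field(default=())

    @property
    def winner(self) -> int:
        return self.order[0]


def validate_matrix(
    raw, labels=None, mode: str = "strict"
) -> PairwiseComparisonMatrix:
    """Validate a raw square grid as a pairwise-comparison matrix.

    Parameters
    ----------
    raw
        Square grid of positive reals, n >= 2.
    labels
        Item names; defaults to ``C1..Cn``.
    mode
        ``"strict"``  — require unit diagonal and exact reciprocity
        (relative tolerance 1e-9).
        ``"repair_reciprocal"`` — overwrite the lower triangle with
        reciprocals of the upper triangle (for files with rounded
        decimals such as 0.33 for 1/3).
        ``"saaty"`` — strict, plus every off-diagonal entry must lie in
        the 17-value admissible set {1/9..1/2, 1, 2..9}.
    """
    a = np.asarray(raw, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise MatrixValidationError(f"input must be square, got shape {a.shape}")
    n = a.shape[0]
    if n < 2:
        raise MatrixValidationError("need at least 2 items to compare")
    if mode not in ("strict", "repair_reciprocal", "saaty"):
        raise ValueError(f"unknown validation mode {mode!r}")
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(n))
    labels = tuple(str(x) for x in labels)
    if len(labels) != n or any(not s for s in labels):
        raise MatrixValidationError("labels must be n non-empty strings")

    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise MatrixValidationError("all entries must be finite and strictly positive")
    if not np.allclose(np.diag(a), 1.0, rtol=0, atol=1e-12):
        raise MatrixValidationError("every diagonal entry must equal 1")

    if mode == "repair_reciprocal":
        a = a.copy()
        iu, ju = np.triu_indices(n, k=1)
        a[ju, iu] = 1.0 / a[iu, ju]
        np.fill_diagonal(a, 1.0)
    else:
        prod = a * a.T
        if not np.allclose(prod, 1.0, rtol=_RECIPROCITY_RTOL, atol=0):
            i, j = np.unravel_index(np.argmax(np.abs(prod - 1.0)), prod.shape)
            raise MatrixValidationError(
                f"reciprocity violated at ({labels[i]}, {labels[j]}): "
                f"{a[i, j]:g} * {a[j, i]:g} != 1"
            )
    if mode == "saaty":
        off = a[~np.eye(n, dtype=bool)]
        dist = np.min(np.abs(off[:, None] - SAATY_VALUES[None, :]), axis=1)
        if np.any(dist > 1e-9):
            bad = off[np.argmax(dist)]
            raise MatrixValidationError(
                f"entry {bad:g} is not on the Saaty scale (1/9..9)"
            )
    return PairwiseComparisonMatrix(a, labels)


def consistent_from_weights(weights, labels=None) -> PairwiseComparisonMatrix:
    """Rank-one consistent matrix a_ij = w_i / w_j built from priorities."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    a = w[:, None] / w[None, :]
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(len(w)))
    return PairwiseComparisonMatrix(a, tuple(labels))


def compute_weights(
    M: PairwiseComparisonMatrix, method: str = "column_norm"
) -> WeightVector:
    """Extract the criterion priority vector from a judgment matrix.

    ``"column_norm"`` divides each entry by its column sum and averages
    across rows (the standard approximate eigenvector).  ``"eigen"``
    computes the principal eigenvector by power iteration.  Both are
    normalized to sum to one and coincide exactly on consistent matrices.
    """
    a = M.entries
    if method == "column_norm":
        w = (a / a.sum(axis=0, keepdims=True)).mean(axis=1)
    elif method == "eigen":
        w = _power_iteration_vector(a)
    else:
        raise ValueError(f"unknown weight method {method!r}")
    w = w / w.sum()
    return WeightVector(w, method=method)


def _power_iteration_vector(a: np.ndarray, tol: float = 1e-12, maxiter: int = 1000):
    v = np.full(a.shape[0], 1.0 / a.shape[0])
    for _ in range(maxiter):
        nxt = a @ v
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - v)) < tol:
            return nxt
        v = nxt
    return v


def lambda_max(
    M: PairwiseComparisonMatrix,
    w: WeightVector | None = None,
    method: str = "mean_ratio",
) -> float:
    """Principal eigenvalue estimate of the judgment matrix.

    ``"mean_ratio"`` averages (A w)_i / w_i over i using the supplied (or
    column-norm) weights.  ``"power"`` runs power iteration to relative
    tolerance 1e-10 (at most 1000 sweeps).  For a perfectly consistent
    matrix both return exactly n.
    """
    a = M.entries
    if method == "mean_ratio":
        if w is None:
            w = compute_weights(M, "column_norm")
        wv = w.weights
        assert np.all(wv > 0), "weights of a positive matrix must be positive"
        return float(np.mean((a @ wv) / wv))
    if method == "power":
        v = np.full(a.shape[0], 1.0 / a.shape[0])
        lam = 0.0
        for _ in range(1000):
            av = a @ v
            new_lam = av.sum()  # Rayleigh-type estimate with sum normalization
            v = av / new_lam
            if abs(new_lam - lam) <= 1e-10 * abs(new_lam):
                break
            lam = new_lam
        return float(lam)
    raise ValueError(f"unknown lambda_max method {method!r}")


def random_index(n: int) -> float:
    """Saaty's Random Index for matrix order n (0 for n <= 2)."""
    if n < 1:
        raise ValueError("matrix order must be positive")
    if n <= 2:
        # 1x1 and 2x2 reciprocal matrices are always consistent.
        return 0.0
    try:
        return RANDOM_INDEX[n]
    except KeyError:
        raise ValueError(
            f"Random Index is tabulated only up to order 10 (got n={n})"
        ) from None


def consistency(
    M: PairwiseComparisonMatrix, method: str = "mean_ratio"
) -> ConsistencyReport:
    """Full consistency diagnostics: lambda_max, CI, RI, CR and verdict.

    CI = (lambda_max - n)/(n - 1) and CR = CI/RI; the matrix is accepted
    when CR <= 0.1.  Orders 1 and 2 are consistent by construction and
    reported with CR = 0.
    """
    n = M.n
    lam = lambda_max(M, method=method)
    if n <= 2:
        return ConsistencyReport(
            lambda_max=lam, ci=0.0, ri=0.0, cr=0.0, consistent=True, n=n
        )
    ci = (lam - n) / (n - 1)
    ri = random_index(n)
    cr = ci / ri
    return ConsistencyReport(
        lambda_max=lam, ci=ci, ri=ri, cr=cr, consistent=bool(cr <= CR_THRESHOLD), n=n
    )


def rank_options(P: ScoreMatrix, w: WeightVector) -> RankedOptions:
    """Rank options by v = P w (descending; ties broken by lowest index)."""
    if P.n != len(w):
        raise ValueError(
            f"score matrix has {P.n} criteria but weight vector has {len(w)}"
        )
    v = P.scores @ w.weights
    # stable sort on -v keeps the lowest index first among ties
    order = tuple(int(i) for i in np.argsort(-v, kind="stable"))
    return RankedOptions(values=v, order=order, option_labels=P.option_labels)
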