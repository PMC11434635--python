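"""Turning an inconsistent judgment matrix into a consistent, faithful one.

A reciprocal n-by-n matrix has only D = n(n-1)/2 free judgments; the search
works on the logarithms of the upper-triangle entries, boxed to
[ln(1/9), ln 9] so a judgment and its reciprocal are symmetric around 0 and
the Saaty grid is nearly uniform.  The hybrid swarm minimizes
OI(decode(x), M) = DI + (lambda_max - n), with one particle warm-started at
the original matrix (the objective rewards closeness to it, so the search
should begin there).  Optionally the continuous optimum is snapped back onto
the discrete Saaty scale and polished by greedy coordinate descent on the
grid; the snapped matrix is kept only if it remains consistent (CR <= 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import (
    CR_THRESHOLD,
    SAATY_VALUES,
    ConsistencyReport,
    PairwiseComparisonMatrix,
    consistency,
)
from .objective import objective_index
from .optimizers import AnnealConfig, OptResult, SwarmConfig, pso_run, pso_sa_run

__all__ = [
    "LOG_BOUNDS",
    "MatrixEncoding",
    "RefinementResult",
    "encode",
    "decode",
    "snap_to_saaty",
    "oi_objective",
    "refine",
]

#: Per-dimension search box on the log scale: judgments stay within [1/9, 9].
LOG_BOUNDS = (float(np.log(1.0 / 9.0)), float(np.log(9.0)))

_LOG_SAATY = np.log(SAATY_VALUES)


@dataclass(frozen=True)
class MatrixEncoding:
    """Log-scale upper-triangle vector representation of a reciprocal matrix."""

    x: np.ndarray
    n: int
    labels: tuple[str, ...]


@dataclass(frozen=True)
class RefinementResult:
    original: PairwiseComparisonMatrix
    refined: PairwiseComparisonMatrix
    report_before: ConsistencyReport
    report_after: ConsistencyReport
    di: float
    oi: float
    trace: np.ndarray
    snapped: bool
    seed: int
    iterations_used: int = 0
    evaluations: int = 0
    #: polished discrete candidate, even when the CR guard rejected it
    snapped_candidate: PairwiseComparisonMatrix | None = None


def encode(M: PairwiseComparisonMatrix, strict: bool = True) -> MatrixEncoding:
    """Log-transform the upper triangle (row-major, i < j) into a vector."""
    iu, ju = np.triu_indices(M.n, k=1)
    upper = M.entries[iu, ju]
    lo, hi = LOG_BOUNDS
    x = np.log(upper)
    if strict and (np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12)):
        raise ValueError("matrix entry outside the [1/9, 9] judgment range")
    return MatrixEncoding(x=np.clip(x, lo, hi), n=M.n, labels=M.labels)


def decode(x: np.ndarray, n: int, labels=None) -> PairwiseComparisonMatrix:
    """Rebuild the reciprocal matrix from log-scale upper-triangle values.

    Values are clamped into the box, exponentiated into the upper triangle;
    the lower triangle is filled with exact reciprocals and the diagonal set
    to 1, so the result is valid by construction.
    """
    x = np.clip(np.asarray(x, dtype=float), *LOG_BOUNDS)
    if len(x) != n * (n - 1) // 2:
        raise ValueError("encoding length must be n(n-1)/2")
    a = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    upper = np.exp(x)
    a[iu, ju] = upper
    a[ju, iu] = 1.0 / upper
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(n))
    return PairwiseComparisonMatrix(a, tuple(labels))


def snap_to_saaty(M: PairwiseComparisonMatrix) -> PairwiseComparisonMatrix:
    """Round every judgment to the nearest Saaty value in log distance.

    Ties between two grid values break toward 1 (the milder judgment).
    Reciprocals are refilled from the snapped upper triangle.
    """
    n = M.n
    iu, ju = np.triu_indices(n, k=1)
    logs = np.log(M.entries[iu, ju])
    dist = np.abs(logs[:, None] - _LOG_SAATY[None, :])
    # tie-break toward 1: among equal distances prefer the smaller |log value|
    keys = dist + 1e-13 * np.abs(_LOG_SAATY)[None, :]
    snapped = SAATY_VALUES[np.argmin(keys, axis=1)]
    a = np.eye(n)
    a[iu, ju] = snapped
    a[ju, iu] = 1.0 / snapped
    return PairwiseComparisonMatrix(a, M.labels)


def oi_objective(M: PairwiseComparisonMatrix):
    """Batched OI evaluator over log-encoded candidates against ``M``.

    Returns a function mapping a (batch, D) array of log upper-triangle
    vectors to a length-batch array of OI values; equivalent to decoding each
    row and calling :func:`ahp_refine.objective.objective_index`, but without
    per-candidate container overhead (the swarm calls it once per generation).
    """
    n = M.n
    iu, ju = np.triu_indices(n, k=1)
    u0 = M.entries[iu, ju]
    denom = n * n - n
    lo, hi = LOG_BOUNDS
    eye = np.eye(n)

    def batch(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        e = np.exp(np.clip(X, lo, hi))
        # DI over the unordered pairs; upper-triangle ratios give the same
        # x + 1/x terms as the lower triangle by reciprocity
        r = e / u0
        di = (r + 1.0 / r).sum(axis=1) / denom - 1.0
        a = np.broadcast_to(eye, (len(X), n, n)).copy()
        a[:, iu, ju] = e
        a[:, ju, iu] = 1.0 / e
        w = (a / a.sum(axis=1, keepdims=True)).mean(axis=2)
        lam = (np.einsum("bij,bj->bi", a, w) / w).mean(axis=1)
        return np.maximum(di, 0.0) + np.maximum(lam - n, 0.0)

    return batch


def _grid_polish(
    M: PairwiseComparisonMatrix, original: PairwiseComparisonMatrix,
    max_sweeps: int = 8,
) -> PairwiseComparisonMatrix:
    """Greedy coordinate descent on the Saaty grid minimizing OI.

    Each sweep tries every admissible value for each upper-triangle judgment
    in turn and keeps any strict improvement; stops at a local optimum.
    """
    obj = oi_objective(original)
    x = encode(M).x.copy()
    best = float(obj(x[None, :])[0])
    for _ in range(max_sweeps):
        improved = False
        for k in range(len(x)):
            cand = np.tile(x, (len(_LOG_SAATY), 1))
            cand[:, k] = _LOG_SAATY
            vals = obj(cand)
            j = int(np.argmin(vals))
            if vals[j] < best - 1e-12:
                best = float(vals[j])
                x[k] = _LOG_SAATY[j]
                improved = True
        if not improved:
            break
    # re-snap so entries are exact grid values, not exp(log(v)) round-off
    return snap_to_saaty(decode(x, M.n, M.labels))


def refine(
    M: PairwiseComparisonMatrix,
    swarm_cfg: SwarmConfig | None = None,
    anneal_cfg: AnnealConfig | None = None,
    snap: bool = True,
    engine: str = "pso_sa",
    callback=None,
) -> RefinementResult:
    """Repair an inconsistent judgment matrix by minimizing OI.

    A matrix that is already consistent is returned unchanged with an empty
    trace.  Otherwise the hybrid swarm (or plain PSO with ``engine="pso"``)
    searches the log-encoded upper triangle, warm-started at the original
    matrix.  With ``snap=True`` the result is discretized to the Saaty scale
    and kept only if its CR stays at or below 0.1; otherwise the continuous
    matrix is returned and ``snapped`` is False.
    """
    if swarm_cfg is None:
        swarm_cfg = SwarmConfig()
    if anneal_cfg is None:
        anneal_cfg = AnnealConfig()
    report_before = consistency(M)
    if report_before.consistent:
        return RefinementResult(
            original=M,
            refined=M,
            report_before=report_before,
            report_after=report_before,
            di=0.0,
            oi=max(report_before.lambda_max - M.n, 0.0),
            trace=np.empty(0),
            snapped=False,
            seed=swarm_cfg.seed,
        )

    n = M.n
    labels = M.labels
    enc = encode(M)
    obj = oi_objective(M)

    kwargs = {"x0": [enc.x], "callback": callback, "vectorized": True}
    if engine == "pso_sa":
        result: OptResult = pso_sa_run(obj, LOG_BOUNDS, swarm_cfg, anneal_cfg, **kwargs)
    elif engine == "pso":
        result = pso_run(obj, LOG_BOUNDS, swarm_cfg, **kwargs)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    refined = decode(result.best_position, n, labels)
    snapped = False
    candidate = None
    if snap:
        candidate = _grid_polish(snap_to_saaty(refined), M)
        if consistency(candidate).cr <= CR_THRESHOLD:
            refined = candidate
            snapped = True

    report_after = consistency(refined)
    obj_val = objective_index(refined, M)
    return RefinementResult(
        original=M,
        refined=refined,
        report_before=report_before,
        report_after=report_after,
        di=obj_val.di,
        oi=obj_val.oi,
        trace=result.trace,
        snapped=snapped,
        seed=swarm_cfg.seed,
        iterations_used=result.iterations_used,
        evaluations=result.evaluations,
        snapped_candidate=candidate,
    )
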