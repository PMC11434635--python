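"""Meal ranking on top of the AHP stack.

Criteria weights come from the (refined-if-needed) judgment matrix; meal
options carry qualitative levels per criterion (high / moderate / low) that
an ordinal scale maps to numbers, column-normalized into the option score
matrix P; the recommendation is the ranking of v = P w.  When per-criterion
pairwise matrices are available instead of qualitative levels, their weight
vectors form the columns of P directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import (
    PairwiseComparisonMatrix,
    RankedOptions,
    ScoreMatrix,
    WeightVector,
    compute_weights,
    consistency,
    rank_options,
)
from .optimizers import AnnealConfig, SwarmConfig
from .refinement import RefinementResult, refine

__all__ = [
    "CriterionSet",
    "MealOption",
    "QualitativeScale",
    "weights_from_refined",
    "score_matrix",
    "score_matrix_from_pairwise",
    "recommend",
]


@dataclass(frozen=True)
class CriterionSet:
    """Ordered criterion labels together with their judgment matrix."""

    labels: tuple[str, ...]
    matrix: PairwiseComparisonMatrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.labels != self.matrix.labels:
            raise ValueError(
                f"criterion labels {self.labels} do not match matrix labels "
                f"{self.matrix.labels}"
            )


@dataclass(frozen=True)
class MealOption:
    """A meal with one qualitative level per criterion."""

    name: str
    qualitative_scores: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualitative_scores", dict(self.qualitative_scores))


@dataclass(frozen=True)
class QualitativeScale:
    """Ordinal level-to-number mapping; must be positive and increasing."""

    mapping: dict = field(
        default_factory=lambda: {"high": 3.0, "moderate": 2.0, "low": 1.0}
    )

    def __post_init__(self) -> None:
        m = dict(self.mapping)
        if any(v <= 0 for v in m.values()):
            raise ValueError("scale values must be strictly positive")
        ordered = [m.get("low"), m.get("moderate"), m.get("high")]
        present = [v for v in ordered if v is not None]
        if sorted(present) != present or len(set(present)) != len(present):
            raise ValueError("scale must increase strictly from low to high")
        object.__setattr__(self, "mapping", m)

    def value(self, level: str) -> float:
        try:
            return float(self.mapping[level])
        except KeyError:
            raise ValueError(f"unknown qualitative level {level!r}") from None


def weights_from_refined(
    criteria: CriterionSet,
    swarm_cfg: SwarmConfig | None = None,
    anneal_cfg: AnnealConfig | None = None,
    snap: bool = True,
) -> tuple[WeightVector, RefinementResult | None]:
    """Criterion weights, refining the matrix first if it is inconsistent.

    Returns the weight vector and the refinement result when refinement ran
    (``None`` when the matrix was already consistent).
    """
    matrix = criteria.matrix
    if consistency(matrix).consistent:
        return compute_weights(matrix), None
    result = refine(matrix, swarm_cfg=swarm_cfg, anneal_cfg=anneal_cfg, snap=snap)
    return compute_weights(result.refined), result


def score_matrix(
    options: list[MealOption],
    scale: QualitativeScale | None = None,
    criteria: tuple[str, ...] | None = None,
) -> ScoreMatrix:
    """Column-normalized option scores from qualitative levels.

    Criterion order defaults to the first option's level keys; every option
    must carry a level for every criterion.
    """
    if not options:
        raise ValueError("need at least one meal option")
    if scale is None:
        scale = QualitativeScale()
    if criteria is None:
        criteria = tuple(options[0].qualitative_scores.keys())
    criteria = tuple(criteria)
    rows = []
    for opt in options:
        missing = [c for c in criteria if c not in opt.qualitative_scores]
        if missing:
            raise ValueError(f"option {opt.name!r} lacks levels for {missing}")
        rows.append([scale.value(opt.qualitative_scores[c]) for c in criteria])
    raw = np.asarray(rows, dtype=float)
    scores = raw / raw.sum(axis=0, keepdims=True)
    return ScoreMatrix(
        scores=scores,
        option_labels=tuple(o.name for o in options),
        criterion_labels=criteria,
    )


def score_matrix_from_pairwise(
    per_criterion: list[PairwiseComparisonMatrix],
    option_labels: tuple[str, ...],
    criterion_labels: tuple[str, ...],
    method: str = "column_norm",
) -> ScoreMatrix:
    """Score matrix from one option-vs-option judgment matrix per criterion.

    Each matrix compares the M options under one criterion; its weight vector
    becomes that criterion's score column (already summing to one).
    """
    if len(per_criterion) != len(criterion_labels):
        raise ValueError("need one pairwise matrix per criterion")
    cols = []
    for mat in per_criterion:
        if mat.n != len(option_labels):
            raise ValueError("per-criterion matrix order must equal option count")
        cols.append(compute_weights(mat, method=method).weights)
    return ScoreMatrix(
        scores=np.column_stack(cols),
        option_labels=tuple(option_labels),
        criterion_labels=tuple(criterion_labels),
    )


def recommend(
    criteria: CriterionSet,
    options: list[MealOption],
    scale: QualitativeScale | None = None,
    swarm_cfg: SwarmConfig | None = None,
    anneal_cfg: AnnealConfig | None = None,
) -> RankedOptions:
    """Rank meal options for a client: v = P w over refined criterion weights."""
    w, _ = weights_from_refined(criteria, swarm_cfg=swarm_cfg, anneal_cfg=anneal_cfg)
    P = score_matrix(options, scale=scale, criteria=criteria.labels)
    return rank_options(P, w)
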