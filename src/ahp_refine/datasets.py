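"""Built-in worked examples: two nutrition-counseling client profiles.

Client 1 is a middle-aged male newly diagnosed with type 2 diabetes; meals
are judged on Glycemic control (GC), Nutrient density (ND), Palatability (P)
and Convenience (C).  Client 2 is an elderly female managing hypertension and
osteoporosis; criteria are Blood pressure management (BPM), Bone health (BH),
Flavor (F) and Ease of preparation (EP).  Each profile ships the
nutritionist's initial judgment matrix (inconsistent, CR > 0.1) and the
published consistent refinement of it, plus illustrative meal options with
qualitative criterion levels.  The contrast meal options are synthetic,
invented here to make the ranking examples two-sided.
"""

from __future__ import annotations

from fractions import Fraction

from .matrices import PairwiseComparisonMatrix, validate_matrix
from .meal_planning import CriterionSet, MealOption

__all__ = [
    "client1_initial",
    "client1_refined",
    "client2_initial",
    "client2_refined",
    "client1_criteria",
    "client2_criteria",
    "client1_meals",
    "client2_meals",
]

_F = Fraction

_CLIENT1_LABELS = ("GC", "ND", "P", "C")
_CLIENT1_INITIAL = [
    [1, 6, 8, 9],
    [_F(1, 6), 1, 3, 5],
    [_F(1, 8), _F(1, 3), 1, 4],
    [_F(1, 9), _F(1, 5), _F(1, 4), 1],
]
_CLIENT1_REFINED = [
    [1, 4, 6, 8],
    [_F(1, 4), 1, 2, 4],
    [_F(1, 6), _F(1, 2), 1, 2],
    [_F(1, 8), _F(1, 4), _F(1, 2), 1],
]

_CLIENT2_LABELS = ("BPM", "BH", "F", "EP")
_CLIENT2_INITIAL = [
    [1, 6, 8, 9],
    [_F(1, 6), 1, 4, 6],
    [_F(1, 8), _F(1, 4), 1, 4],
    [_F(1, 9), _F(1, 6), _F(1, 4), 1],
]
_CLIENT2_REFINED = [
    [1, 3, 6, 8],
    [_F(1, 3), 1, 3, 4],
    [_F(1, 6), _F(1, 3), 1, 2],
    [_F(1, 8), _F(1, 4), _F(1, 2), 1],
]


def _build(grid, labels) -> PairwiseComparisonMatrix:
    return validate_matrix([[float(x) for x in row] for row in grid], labels=labels)


def client1_initial() -> PairwiseComparisonMatrix:
    """Initial GC/ND/P/C judgments for the diabetic client (inconsistent)."""
    return _build(_CLIENT1_INITIAL, _CLIENT1_LABELS)


def client1_refined() -> PairwiseComparisonMatrix:
    """Published consistent refinement of the client-1 judgments (CR ~ 0.017)."""
    return _build(_CLIENT1_REFINED, _CLIENT1_LABELS)


def client2_initial() -> PairwiseComparisonMatrix:
    """Initial BPM/BH/F/EP judgments for the elderly client (CR ~ 0.14)."""
    return _build(_CLIENT2_INITIAL, _CLIENT2_LABELS)


def client2_refined() -> PairwiseComparisonMatrix:
    """Published consistent refinement of the client-2 judgments (CR ~ 0.015)."""
    return _build(_CLIENT2_REFINED, _CLIENT2_LABELS)


def client1_criteria() -> CriterionSet:
    return CriterionSet(labels=_CLIENT1_LABELS, matrix=client1_initial())


def client2_criteria() -> CriterionSet:
    return CriterionSet(labels=_CLIENT2_LABELS, matrix=client2_initial())


def client1_meals() -> list[MealOption]:
    """Mediterranean lunch options for client 1 (second option synthetic)."""
    return [
        MealOption(
            name="grilled chicken salad",
            qualitative_scores={
                "GC": "high", "ND": "high", "P": "moderate", "C": "moderate",
            },
        ),
        MealOption(
            name="white pasta alfredo",
            qualitative_scores={
                "GC": "low", "ND": "low", "P": "high", "C": "high",
            },
        ),
    ]


def client2_meals() -> list[MealOption]:
    """Plant-based options for client 2 (second option synthetic)."""
    return [
        MealOption(
            name="kale and quinoa salad",
            qualitative_scores={
                "BPM": "high", "BH": "high", "F": "moderate", "EP": "high",
            },
        ),
        MealOption(
            name="canned vegetable soup",
            qualitative_scores={
                "BPM": "low", "BH": "moderate", "F": "moderate", "EP": "high",
            },
        ),
    ]
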