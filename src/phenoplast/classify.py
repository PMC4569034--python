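"""Threshold decision tree assigning each block one of five patterns.

The classifier applies a single effect-size cutoff theta (by convention
the mean coefficient of variation across all cells of the dataset; 0.53
in the plant reciprocal-transplant synthesis) to the standardized
metrics:

1. A *pair* is plastic iff its plasticity metric exceeds theta (ties go
   to NOT_PLASTIC).  A *block* is plastic only if **both** pairs are.
2. Nonplastic blocks split on the differentiation metric:
   CANALIZED_NO_DIFF (<= theta) vs CANALIZED_DIFF (> theta).
3. Plastic blocks split on an adaptiveness score:
   PERFECT_ADAPTIVE (<= theta), ADAPTIVE (theta < score < 1),
   NONADAPTIVE (>= 1).  The score is either the larger of the two
   per-pair adaptiveness values (``ScoreMode.PAIR_MAX``, default) or the
   block-level metric (``ScoreMode.BLOCK``); under the standardizations
   used here the two coincide, and both are kept so either reporting
   convention can be requested explicitly.
4. NONADAPTIVE blocks are subtyped per population: STEEP reaction norms
   overshoot the resident optimum in the right direction; WRONG_SIGN
   norms move away from it.  For population A the verbatim conditions
   are: STEEP iff (AinA>BinB and AinB<BinB) or (AinA<BinB and AinB>BinB);
   WRONG_SIGN iff (AinA>BinB and AinB>AinA) or (AinA<BinB and AinB<AinA).
   Population B mirrors the labels.

Blocks whose metrics are degenerate (a zero standardizer) are labeled
UNCLASSIFIED and excluded from every frequency denominator.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .metrics import (
    MetricResult,
    block_adaptiveness,
    pair_adaptiveness,
    pair_plasticity,
    population_differentiation,
)
from .records import PairedRecord, TraitBlock, normalize_dispersion

__all__ = [
    "DEFAULT_THETA",
    "Threshold",
    "Pattern",
    "Subtype",
    "PairClass",
    "ScoreMode",
    "PatternLabel",
    "BlockClassification",
    "derive_threshold",
    "classify_pair",
    "classify_block",
    "classify_blocks",
    "classify_nonadaptive_subtype",
]

#: Conventional cutoff: the mean CV of the synthesis dataset, equivalent
#: to a one-standard-deviation shift (significant at p < 0.05 for n = 10).
DEFAULT_THETA = 0.53


@dataclass(frozen=True)
class Threshold:
    """Effect-size cutoff separating "no response" from "response"."""

    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be a positive real, got {self.theta!r}")


class Pattern(str, enum.Enum):
    CANALIZED_NO_DIFF = "canalized_no_diff"
    CANALIZED_DIFF = "canalized_diff"
    PERFECT_ADAPTIVE = "perfect_adaptive"
    ADAPTIVE = "adaptive"
    NONADAPTIVE = "nonadaptive"
    UNCLASSIFIED = "unclassified"


class Subtype(str, enum.Enum):
    STEEP = "steep"
    WRONG_SIGN = "wrong_sign"
    NONE = "none"


class PairClass(str, enum.Enum):
    PLASTIC = "plastic"
    NOT_PLASTIC = "not_plastic"
    UNCLASSIFIED = "unclassified"


class ScoreMode(str, enum.Enum):
    """How a plastic block's adaptiveness score is computed."""

    PAIR_MAX = "pair_max"  # larger of the two per-pair adaptiveness values
    BLOCK = "block"  # the block-level metric


@dataclass(frozen=True)
class PatternLabel:
    category: Pattern
    subtype: Subtype = Subtype.NONE

    def __post_init__(self) -> None:
        if self.subtype is not Subtype.NONE and self.category is not Pattern.NONADAPTIVE:
            raise ValueError("only NONADAPTIVE blocks carry a steep/wrong-sign subtype")


def derive_threshold(blocks: Iterable[TraitBlock]) -> Threshold:
    """Mean coefficient of variation (SD/|mean|) over every cell.

    Cells with a zero mean have an undefined CV and are excluded with a
    warning; an input with no usable cell raises.
    """
    cvs: list[float] = []
    skipped = 0
    for block in blocks:
        for cell in block.cells.values():
            if cell.mean == 0:
                skipped += 1
                continue
            cvs.append(normalize_dispersion(cell, "SD").dispersion_value / abs(cell.mean))
    if skipped:
        warnings.warn(f"excluded {skipped} zero-mean cell(s) from the CV average", stacklevel=2)
    if not cvs:
        raise ValueError("no cells with nonzero mean: threshold undefined")
    return Threshold(sum(cvs) / len(cvs))


def classify_pair(pair: PairedRecord, theta: Threshold | float) -> PairClass:
    """Plastic iff the pair's plasticity metric strictly exceeds theta."""
    theta = theta.theta if isinstance(theta, Threshold) else float(theta)
    result = pair_plasticity(pair.resident.mean, pair.nonresident.mean, pair.population)
    return _pair_class(result, theta)


def _pair_class(result: MetricResult, theta: float) -> PairClass:
    if result.degenerate:
        return PairClass.UNCLASSIFIED
    return PairClass.PLASTIC if result.value > theta else PairClass.NOT_PLASTIC


def classify_nonadaptive_subtype(block: TraitBlock, population: str) -> Subtype:
    """Steep vs wrong-sign subtype for one population of a nonadaptive block."""
    aina, ainb, binb, bina = block.means
    if population == "A":
        return _subtype(aina, ainb, binb)
    if population == "B":
        return _subtype(binb, bina, aina)
    raise ValueError(f"population must be 'A' or 'B', got {population!r}")


def _subtype(own_res: float, own_nonres: float, other_res: float) -> Subtype:
    # Written for population A; population B passes mirrored arguments.
    if (own_res > other_res and own_nonres < other_res) or (
        own_res < other_res and own_nonres > other_res
    ):
        return Subtype.STEEP
    if (own_res > other_res and own_nonres > own_res) or (
        own_res < other_res and own_nonres < own_res
    ):
        return Subtype.WRONG_SIGN
    # Unreachable for a plastic pair with adaptiveness >= 1: the
    # nonresident mean would have to sit strictly between the two
    # resident means (score < 1) or coincide with one of them
    # (score 0, or a nonplastic pair).
    raise AssertionError(
        "steep/wrong-sign conditions do not partition this configuration: "
        f"own_res={own_res}, own_nonres={own_nonres}, other_res={other_res}"
    )


@dataclass(frozen=True)
class BlockClassification:
    """Full classifier output for one block, metrics included."""

    block: TraitBlock
    theta: float
    score_mode: ScoreMode
    pair_class_a: PairClass
    pair_class_b: PairClass
    label: PatternLabel
    subtype_a: Subtype
    subtype_b: Subtype
    metrics: dict[str, MetricResult]
    score: float | None  # adaptiveness score, plastic blocks only

    @property
    def category(self) -> Pattern:
        return self.label.category

    @property
    def study_id(self) -> str:
        return self.block.study_id

    @property
    def trait_category(self):
        return self.block.trait_category


def classify_block(
    block: TraitBlock,
    theta: Threshold | float = DEFAULT_THETA,
    score_mode: ScoreMode | str = ScoreMode.PAIR_MAX,
) -> BlockClassification:
    """Run the full decision tree on one block."""
    th = theta.theta if isinstance(theta, Threshold) else float(theta)
    mode = ScoreMode(score_mode)
    aina, ainb, binb, bina = block.means

    plast_a = pair_plasticity(aina, ainb, "A")
    plast_b = pair_plasticity(binb, bina, "B")
    diff = population_differentiation(aina, binb)
    adapt_a = pair_adaptiveness(aina, ainb, binb, "A")
    adapt_b = pair_adaptiveness(binb, bina, aina, "B")
    adapt_block = block_adaptiveness(block)
    metrics = {
        "plasticity_A": plast_a,
        "plasticity_B": plast_b,
        "differentiation": diff,
        "adaptiveness_A": adapt_a,
        "adaptiveness_B": adapt_b,
        "block_adaptiveness": adapt_block,
    }

    cls_a = _pair_class(plast_a, th)
    cls_b = _pair_class(plast_b, th)

    def result(label: PatternLabel, sub_a=Subtype.NONE, sub_b=Subtype.NONE, score=None):
        return BlockClassification(
            block, th, mode, cls_a, cls_b, label, sub_a, sub_b, metrics, score
        )

    if PairClass.UNCLASSIFIED in (cls_a, cls_b):
        return result(PatternLabel(Pattern.UNCLASSIFIED))

    if not (cls_a is PairClass.PLASTIC and cls_b is PairClass.PLASTIC):
        if diff.degenerate:
            return result(PatternLabel(Pattern.UNCLASSIFIED))
        category = (
            Pattern.CANALIZED_NO_DIFF if diff.value <= th else Pattern.CANALIZED_DIFF
        )
        return result(PatternLabel(category))

    if adapt_a.degenerate or adapt_b.degenerate or adapt_block.degenerate:
        return result(PatternLabel(Pattern.UNCLASSIFIED))

    score = (
        max(adapt_a.value, adapt_b.value)
        if mode is ScoreMode.PAIR_MAX
        else adapt_block.value
    )
    if score <= th:
        return result(PatternLabel(Pattern.PERFECT_ADAPTIVE), score=score)
    if score < 1.0:
        return result(PatternLabel(Pattern.ADAPTIVE), score=score)

    sub_a = (
        classify_nonadaptive_subtype(block, "A") if adapt_a.value >= 1.0 else Subtype.NONE
    )
    sub_b = (
        classify_nonadaptive_subtype(block, "B") if adapt_b.value >= 1.0 else Subtype.NONE
    )
    # Block-level subtype: wrong-sign dominates when the populations disagree.
    block_sub = (
        Subtype.WRONG_SIGN if Subtype.WRONG_SIGN in (sub_a, sub_b) else Subtype.STEEP
    )
    return result(
        PatternLabel(Pattern.NONADAPTIVE, block_sub), sub_a, sub_b, score=score
    )


def classify_blocks(
    blocks: Sequence[TraitBlock],
    theta: Threshold | float = DEFAULT_THETA,
    score_mode: ScoreMode | str = ScoreMode.PAIR_MAX,
) -> list[BlockClassification]:
    """Classify every block at a common threshold."""
    return [classify_block(b, theta, score_mode) for b in blocks]
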