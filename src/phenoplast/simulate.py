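"""Synthetic reciprocal-transplant blocks with known evolutionary patterns.

Every pipeline stage is testable without external data because this
module generates labeled blocks under each of the five evolutionary
scenarios (canalized with/without population differentiation; perfect
adaptive, adaptive, and nonadaptive plasticity, the latter in steep and
wrong-sign variants).  True cell means are solved *analytically* from the
target effect sizes — never sampled and filtered, which would bias
scenario difficulty — so in the noise-free limit the standardized metrics
hit their targets exactly and classification recovers the generating
label with certainty.

Geometry (population A's resident mean ``a`` = ``base_mean``; ``p`` is
the target plasticity of pair A, ``s`` the target adaptiveness of both
pairs, ``d`` the target differentiation of canalized blocks):

* canalized: ``a = m(1+d/2)``, ``b = m(1-d/2)``, each nonresident mean
  shifted by the sub-threshold fraction ``p`` of its resident mean.
* plastic (perfect / adaptive / steep): resident gap ``D = p*a/(1+s)``,
  ``b = a - D``; the transplants overshoot the other population's
  resident mean by ``s*D`` (``AinB = b - s*D``, ``BinA = a + s*D``).
* wrong sign: ``D = p*a/(s-1)``; transplants move *away* from the other
  resident mean (``AinB = b + s*D`` lands beyond ``a``; ``BinA = a - s*D``
  lands below ``b``).

One asymmetry is inherent to the standardizations: pair B's plasticity
comes out as ``p*a/b`` rather than ``p`` (exact equality for both pairs
is impossible once the resident means differ), which is always *larger*
than ``p``, so plastic blocks stay plastic whenever ``p`` exceeds the
threshold.  Observed cell means add Gaussian sampling noise with
SD = ``noise_cv * true_mean / sqrt(n_per_cell)``; the SE recorded in each
cell is that same honest value, so the derived threshold (mean CV) of a
noise-free constant-CV dataset equals ``noise_cv`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_THETA,
    BlockClassification,
    Pattern,
    PatternLabel,
    ScoreMode,
    Subtype,
    classify_blocks,
)
from .records import CELL_KEYS, CellMeasure, TraitBlock, TraitCategory

__all__ = [
    "SCENARIOS",
    "SCENARIO_DEFAULTS",
    "TRAIT_CATEGORY_PROBS",
    "ScenarioSpec",
    "LabeledDataset",
    "RecoveryReport",
    "scenario_label",
    "assigned_scenario",
    "true_cell_means",
    "generate_block",
    "generate_dataset",
    "recovery_report",
]

SCENARIOS = (
    "canalized_no_diff",
    "canalized_diff",
    "perfect_adaptive",
    "adaptive",
    "nonadaptive_steep",
    "nonadaptive_wrong_sign",
)

#: Per-scenario default effect sizes: chosen once so that all true cell
#: means are positive and every target sits well clear (margin >= 0.2)
#: of the classification boundaries at theta = 0.53 and 1.
SCENARIO_DEFAULTS: dict[str, dict[str, float | None]] = {
    "canalized_no_diff": dict(plasticity_effect=0.1, differentiation_effect=0.0, adaptiveness_score=None),
    "canalized_diff": dict(plasticity_effect=0.1, differentiation_effect=1.2, adaptiveness_score=None),
    "perfect_adaptive": dict(plasticity_effect=0.9, differentiation_effect=None, adaptiveness_score=0.2),
    "adaptive": dict(plasticity_effect=0.8, differentiation_effect=None, adaptiveness_score=0.75),
    "nonadaptive_steep": dict(plasticity_effect=0.9, differentiation_effect=None, adaptiveness_score=1.8),
    "nonadaptive_wrong_sign": dict(plasticity_effect=0.6, differentiation_effect=None, adaptiveness_score=3.0),
}

#: Life-history / morphological / physiological mixture of the synthesis
#: dataset (50.8 / 43.6 / 5.5, renormalized).
TRAIT_CATEGORY_PROBS: dict[TraitCategory, float] = {
    TraitCategory.LIFE_HISTORY: 0.508,
    TraitCategory.MORPHOLOGICAL: 0.436,
    TraitCategory.PHYSIOLOGICAL: 0.055,
}

_LABELS: dict[str, PatternLabel] = {
    "canalized_no_diff": PatternLabel(Pattern.CANALIZED_NO_DIFF),
    "canalized_diff": PatternLabel(Pattern.CANALIZED_DIFF),
    "perfect_adaptive": PatternLabel(Pattern.PERFECT_ADAPTIVE),
    "adaptive": PatternLabel(Pattern.ADAPTIVE),
    "nonadaptive_steep": PatternLabel(Pattern.NONADAPTIVE, Subtype.STEEP),
    "nonadaptive_wrong_sign": PatternLabel(Pattern.NONADAPTIVE, Subtype.WRONG_SIGN),
}


def scenario_label(scenario: str) -> PatternLabel:
    """The pattern label a noise-free block of this scenario must receive."""
    return _LABELS[scenario]


@dataclass(frozen=True)
class ScenarioSpec:
    """Targets and sampling settings for one generated block.

    Effect-size fields left as None take the per-scenario defaults in
    :data:`SCENARIO_DEFAULTS`.  ``theta`` is the classification cutoff
    the targets must be consistent with; contradictory targets raise
    before any sampling.
    """

    scenario: str
    base_mean: float = 10.0
    plasticity_effect: float | None = None
    differentiation_effect: float | None = None
    adaptiveness_score: float | None = None
    noise_cv: float = 0.05
    n_per_cell: int = 50
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        defaults = SCENARIO_DEFAULTS[self.scenario]
        for name in ("plasticity_effect", "differentiation_effect", "adaptiveness_score"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, defaults[name])
        if not (self.base_mean > 0):
            raise ValueError("base_mean must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_per_cell < 10:
            raise ValueError("n_per_cell must be >= 10 (study inclusion rule)")
        self._validate_targets()
        true_cell_means(self)  # geometric admissibility (positive means)

    def _validate_targets(self) -> None:
        p, s, d, th = (
            self.plasticity_effect,
            self.adaptiveness_score,
            self.differentiation_effect,
            self.theta,
        )
        scen = self.scenario
        if scen in ("canalized_no_diff", "canalized_diff"):
            if p is None or not (0 <= p <= th):
                raise ValueError(f"{scen}: plasticity_effect must lie in [0, theta], got {p}")
            if scen == "canalized_no_diff" and not (d is not None and 0 <= d <= th):
                raise ValueError(f"{scen}: differentiation_effect must lie in [0, theta], got {d}")
            if scen == "canalized_diff" and not (d is not None and d > th):
                raise ValueError(f"{scen}: differentiation_effect must exceed theta, got {d}")
            return
        if p is None or not (p > th):
            raise ValueError(f"{scen}: plasticity_effect must exceed theta, got {p}")
        if scen == "perfect_adaptive" and not (s is not None and 0 <= s <= th):
            raise ValueError(f"{scen}: adaptiveness_score must lie in [0, theta], got {s}")
        if scen == "adaptive" and not (s is not None and th < s < 1):
            raise ValueError(f"{scen}: adaptiveness_score must lie in (theta, 1), got {s}")
        if scen == "nonadaptive_steep" and not (s is not None and s >= 1):
            raise ValueError(f"{scen}: adaptiveness_score must be >= 1, got {s}")
        if scen == "nonadaptive_wrong_sign" and not (s is not None and s > 1):
            raise ValueError(f"{scen}: adaptiveness_score must exceed 1, got {s}")


def true_cell_means(spec: ScenarioSpec) -> dict[str, float]:
    """Noise-free cell means hitting the spec's targets exactly.

    Raises if the targets force a nonpositive trait mean (inadmissible
    geometry for the requested effect sizes).
    """
    m = spec.base_mean
    p = float(spec.plasticity_effect)  # type: ignore[arg-type]
    scen = spec.scenario

    if scen in ("canalized_no_diff", "canalized_diff"):
        d = float(spec.differentiation_effect)  # type: ignore[arg-type]
        a = m * (1 + d / 2)
        b = m * (1 - d / 2)
        means = {"AinA": a, "AinB": a * (1 - p), "BinB": b, "BinA": b * (1 + p)}
    else:
        s = float(spec.adaptiveness_score)  # type: ignore[arg-type]
        a = m
        if scen == "nonadaptive_wrong_sign":
            D = p * a / (s - 1)
            means = {"AinA": a, "AinB": a - D + s * D, "BinB": a - D, "BinA": a - s * D}
        else:
            D = p * a / (1 + s)
            means = {"AinA": a, "AinB": a - D - s * D, "BinB": a - D, "BinA": a + s * D}
    if min(means.values()) <= 0:
        raise ValueError(
            f"{scen}: targets (p={spec.plasticity_effect}, s={spec.adaptiveness_score}, "
            f"d={spec.differentiation_effect}) force a nonpositive cell mean: {means}"
        )
    return means


def generate_block(
    spec: ScenarioSpec,
    seed: int | np.random.Generator | None = None,
    study_id: str = "S01",
    trait_name: str = "trait_01",
    trait_category: TraitCategory | str = TraitCategory.LIFE_HISTORY,
) -> tuple[TraitBlock, PatternLabel]:
    """One block under the scenario, plus its true pattern label."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = true_cell_means(spec)
    cells = {}
    for key in CELL_KEYS:
        true_mean = truth[key]
        sem = spec.noise_cv * abs(true_mean) / math.sqrt(spec.n_per_cell)
        observed = true_mean + rng.normal(0.0, sem) if sem > 0 else true_mean
        cells[key] = CellMeasure(observed, sem, "SE", spec.n_per_cell)
    block = TraitBlock(study_id, trait_name, TraitCategory(trait_category), cells)
    return block, scenario_label(spec.scenario)


@dataclass
class LabeledDataset:
    """Generated blocks with their true scenario labels, one-to-one."""

    blocks: list[TraitBlock]
    true_scenarios: list[str]
    mixture: Mapping[str, float]
    seed: int | None
    specs: list[ScenarioSpec] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.true_scenarios):
            raise ValueError("labels and blocks must align one-to-one")

    @property
    def true_labels(self) -> list[PatternLabel]:
        return [scenario_label(s) for s in self.true_scenarios]

    def __len__(self) -> int:
        return len(self.blocks)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [b.study_id for b in self.blocks],
                "trait_name": [b.trait_name for b in self.blocks],
                "true_scenario": self.true_scenarios,
            }
        )


def generate_dataset(
    mixture: Mapping[str, float],
    n_blocks: int,
    seed: int | None = None,
    base_spec: ScenarioSpec | None = None,
    **spec_overrides,
) -> LabeledDataset:
    """A mixture of scenarios with synthetic study structure.

    Scenarios are drawn per block from the normalized ``mixture``
    weights; trait categories follow the synthesis composition
    (:data:`TRAIT_CATEGORY_PROBS`); blocks are grouped into synthetic
    studies whose sizes are 1 + Poisson(2) (median ~3 traits per study).
    ``spec_overrides`` (e.g. ``noise_cv=0``, ``n_per_cell=20``) apply to
    every scenario's spec.  Fully deterministic given ``seed``.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    names = [s for s in SCENARIOS if mixture.get(s, 0) > 0]
    weights = np.array([mixture[s] for s in names], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0 or set(mixture) - set(SCENARIOS):
        raise ValueError(f"mixture must be nonnegative weights over {SCENARIOS}")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    scenarios = [names[i] for i in rng.choice(len(names), size=n_blocks, p=weights)]

    cats = list(TRAIT_CATEGORY_PROBS)
    cat_p = np.array(list(TRAIT_CATEGORY_PROBS.values()))
    cat_p = cat_p / cat_p.sum()
    categories = [cats[i] for i in rng.choice(len(cats), size=n_blocks, p=cat_p)]

    # Synthetic study structure: sizes 1 + Poisson(2).
    study_of_block: list[int] = []
    study = 0
    while len(study_of_block) < n_blocks:
        size = 1 + rng.poisson(2)
        study_of_block.extend([study] * size)
        study += 1
    study_of_block = study_of_block[:n_blocks]

    proto = base_spec or ScenarioSpec(SCENARIOS[0])
    blocks, specs = [], []
    trait_counter: dict[int, int] = {}
    for i, scen in enumerate(scenarios):
        kwargs = dict(
            scenario=scen,
            plasticity_effect=None,
            differentiation_effect=None,
            adaptiveness_score=None,
        )
        kwargs.update(spec_overrides)
        spec = replace(proto, **kwargs)
        sid = study_of_block[i]
        trait_counter[sid] = trait_counter.get(sid, 0) + 1
        block, _ = generate_block(
            spec,
            rng,
            study_id=f"S{sid + 1:03d}",
            trait_name=f"trait_{trait_counter[sid]:02d}",
            trait_category=categories[i],
        )
        blocks.append(block)
        specs.append(spec)
    return LabeledDataset(blocks, scenarios, dict(mixture), seed, specs)


def assigned_scenario(classification: BlockClassification) -> str:
    """Map a classifier output back onto a scenario name (or 'unclassified')."""
    cat = classification.category
    if cat is Pattern.NONADAPTIVE:
        return (
            "nonadaptive_wrong_sign"
            if classification.label.subtype is Subtype.WRONG_SIGN
            else "nonadaptive_steep"
        )
    return cat.value


@dataclass
class RecoveryReport:
    """Confusion matrix of true vs assigned scenarios plus recovery rates."""

    confusion: pd.DataFrame  # rows: true scenario; columns: assigned
    recovery: dict[str, float]  # diagonal fraction per true scenario
    accuracy: float


def recovery_report(
    dataset: LabeledDataset,
    theta: float = DEFAULT_THETA,
    score_mode: ScoreMode | str = ScoreMode.PAIR_MAX,
) -> RecoveryReport:
    """Classify a labeled dataset and tabulate label recovery."""
    assigned = [
        assigned_scenario(c) for c in classify_blocks(dataset.blocks, theta, score_mode)
    ]
    columns = list(SCENARIOS) + ["unclassified"]
    confusion = pd.DataFrame(0, index=list(SCENARIOS), columns=columns, dtype=int)
    for true, got in zip(dataset.true_scenarios, assigned):
        confusion.loc[true, got] += 1
    totals = confusion.sum(axis=1)
    recovery = {
        s: float(confusion.loc[s, s] / totals[s]) for s in SCENARIOS if totals[s] > 0
    }
    accuracy = float(
        sum(confusion.loc[s, s] for s in SCENARIOS) / max(int(totals.sum()), 1)
    )
    return RecoveryReport(confusion, recovery, accuracy)
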