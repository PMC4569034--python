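"""Frequency summaries, threshold sensitivity sweeps and clustering checks.

The reporting layer turns classified blocks into the synthesis-style
frequency table: pair- and block-level nonplastic percentages, the two
canalized subcategories as percentages of all classified blocks, the
three plastic subcategories as percentages of plastic blocks, and the
steep/wrong-sign split as percentages of nonadaptive blocks — overall
and stratified by trait category.  Percentages are stored at full
precision; :func:`render_table` rounds to one decimal for display.

Because the threshold is a convention, :func:`sensitivity_sweep` re-runs
the classifier at halved and doubled cutoffs (0.265 / 0.53 / 1.06 by
default).  :func:`within_study_clustering_test` checks whether patterns
cluster within studies — traits from one study are not independent, and
strong clustering would mean the frequencies are driven by a few studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_THETA,
    BlockClassification,
    PairClass,
    Pattern,
    ScoreMode,
    Subtype,
    Threshold,
    classify_blocks,
)
from .records import TraitBlock

__all__ = [
    "FrequencyTable",
    "ClusteringReport",
    "summarize",
    "sensitivity_sweep",
    "frequency_frame",
    "render_table",
    "within_study_clustering_test",
]


def _pct(count: int, total: int) -> float | None:
    """Percentage, or None when the denominator is empty (undefined, not 0)."""
    return 100.0 * count / total if total else None


@dataclass
class FrequencyTable:
    """Pattern frequencies at one threshold, with per-trait-category strata."""

    theta: float
    score_mode: ScoreMode
    n_pairs: int
    n_blocks: int
    n_unclassified: int
    pct_pair_not_plastic: float | None
    pct_block_not_plastic: float | None
    pct_canalized_no_diff: float | None  # of all classified blocks
    pct_canalized_diff: float | None  # of all classified blocks
    pct_perfect: float | None  # of plastic blocks
    pct_adaptive: float | None
    pct_nonadaptive: float | None
    pct_steep: float | None  # of nonadaptive blocks
    pct_wrong_sign: float | None
    by_category: dict[str, "FrequencyTable"] = field(default_factory=dict)


def _summarize_group(
    items: Sequence[BlockClassification], theta: float, score_mode: ScoreMode
) -> FrequencyTable:
    classified = [c for c in items if c.category is not Pattern.UNCLASSIFIED]
    n_blocks = len(classified)
    n_unclassified = len(items) - n_blocks

    pair_classes = [
        pc
        for c in items
        for pc in (c.pair_class_a, c.pair_class_b)
        if pc is not PairClass.UNCLASSIFIED
    ]
    n_pairs = len(pair_classes)
    pair_not_plastic = sum(pc is PairClass.NOT_PLASTIC for pc in pair_classes)

    counts = {p: sum(c.category is p for c in classified) for p in Pattern}
    not_plastic = counts[Pattern.CANALIZED_NO_DIFF] + counts[Pattern.CANALIZED_DIFF]
    plastic = (
        counts[Pattern.PERFECT_ADAPTIVE]
        + counts[Pattern.ADAPTIVE]
        + counts[Pattern.NONADAPTIVE]
    )
    nonadaptive = [c for c in classified if c.category is Pattern.NONADAPTIVE]
    steep = sum(c.label.subtype is Subtype.STEEP for c in nonadaptive)
    wrong = sum(c.label.subtype is Subtype.WRONG_SIGN for c in nonadaptive)

    return FrequencyTable(
        theta=theta,
        score_mode=score_mode,
        n_pairs=n_pairs,
        n_blocks=n_blocks,
        n_unclassified=n_unclassified,
        pct_pair_not_plastic=_pct(pair_not_plastic, n_pairs),
        pct_block_not_plastic=_pct(not_plastic, n_blocks),
        pct_canalized_no_diff=_pct(counts[Pattern.CANALIZED_NO_DIFF], n_blocks),
        pct_canalized_diff=_pct(counts[Pattern.CANALIZED_DIFF], n_blocks),
        pct_perfect=_pct(counts[Pattern.PERFECT_ADAPTIVE], plastic),
        pct_adaptive=_pct(counts[Pattern.ADAPTIVE], plastic),
        pct_nonadaptive=_pct(counts[Pattern.NONADAPTIVE], plastic),
        pct_steep=_pct(steep, len(nonadaptive)),
        pct_wrong_sign=_pct(wrong, len(nonadaptive)),
    )


def summarize(
    labels: Sequence[BlockClassification],
    theta: float | Threshold | None = None,
    score_mode: ScoreMode | str | None = None,
) -> FrequencyTable:
    """Frequency table over classified blocks, overall and by trait category.

    ``theta`` and ``score_mode`` default to the values carried by the
    classifications themselves; passing them explicitly only documents
    intent (they must match).
    """
    if not labels:
        raise ValueError("summarize requires at least one classification")
    th = labels[0].theta if theta is None else (
        theta.theta if isinstance(theta, Threshold) else float(theta)
    )
    mode = labels[0].score_mode if score_mode is None else ScoreMode(score_mode)
    if any(not math.isclose(c.theta, th) or c.score_mode is not mode for c in labels):
        raise ValueError("classifications were not all produced at the stated settings")

    table = _summarize_group(labels, th, mode)
    strata: dict[str, list[BlockClassification]] = {}
    for c in labels:
        strata.setdefault(c.trait_category.value, []).append(c)
    table.by_category = {
        name: _summarize_group(items, th, mode) for name, items in sorted(strata.items())
    }
    return table


def sensitivity_sweep(
    blocks: Sequence[TraitBlock],
    thetas: Sequence[float] | None = None,
    score_mode: ScoreMode | str = ScoreMode.PAIR_MAX,
    base_theta: float = DEFAULT_THETA,
) -> list[FrequencyTable]:
    """Classify and summarize at several thresholds (default theta/2, theta, 2*theta)."""
    if thetas is None:
        thetas = (base_theta / 2.0, base_theta, 2.0 * base_theta)
    if any(t <= 0 for t in thetas):
        raise ValueError("all thresholds must be positive")
    return [summarize(classify_blocks(blocks, t, score_mode)) for t in thetas]


_SCALAR_FIELDS = (
    "theta",
    "n_pairs",
    "n_blocks",
    "n_unclassified",
    "pct_pair_not_plastic",
    "pct_block_not_plastic",
    "pct_canalized_no_diff",
    "pct_canalized_diff",
    "pct_perfect",
    "pct_adaptive",
    "pct_nonadaptive",
    "pct_steep",
    "pct_wrong_sign",
)


def frequency_frame(tables: Sequence[FrequencyTable] | FrequencyTable) -> pd.DataFrame:
    """Flatten one or more frequency tables (strata included) into a DataFrame."""
    if isinstance(tables, FrequencyTable):
        tables = [tables]
    rows = []
    for table in tables:
        for stratum, t in [("all", table), *table.by_category.items()]:
            row = {"stratum": stratum, "score_mode": t.score_mode.value}
            row.update({f: getattr(t, f) for f in _SCALAR_FIELDS})
            rows.append(row)
    return pd.DataFrame(rows)


def _fmt(value: float | None) -> str:
    return "--" if value is None else f"{value:.1f}"


def render_table(table: FrequencyTable) -> str:
    """Plain-text rendering, percentages to one decimal place."""
    lines = [
        f"threshold = {table.theta:g}   score mode = {table.score_mode.value}",
        f"(A) Records by pair      N = {table.n_pairs}",
        f"    not plastic {_fmt(table.pct_pair_not_plastic):>6}   "
        f"plastic {_fmt(None if table.pct_pair_not_plastic is None else 100 - table.pct_pair_not_plastic):>6}",
        f"(B) Records by block     N = {table.n_blocks}"
        + (f"   (unclassified: {table.n_unclassified})" if table.n_unclassified else ""),
        f"    canalized, no differentiation  {_fmt(table.pct_canalized_no_diff):>6}  % of blocks",
        f"    canalized, differentiation     {_fmt(table.pct_canalized_diff):>6}  % of blocks",
        f"    perfect adaptive plasticity    {_fmt(table.pct_perfect):>6}  % of plastic",
        f"    adaptive plasticity            {_fmt(table.pct_adaptive):>6}  % of plastic",
        f"    nonadaptive plasticity         {_fmt(table.pct_nonadaptive):>6}  % of plastic",
        f"      steep                        {_fmt(table.pct_steep):>6}  % of nonadaptive",
        f"      wrong sign                   {_fmt(table.pct_wrong_sign):>6}  % of nonadaptive",
    ]
    for name, sub in table.by_category.items():
        lines.append(
            f"    [{name}] n={sub.n_blocks}  not plastic {_fmt(sub.pct_block_not_plastic)}"
            f"  perfect {_fmt(sub.pct_perfect)}  adaptive {_fmt(sub.pct_adaptive)}"
            f"  nonadaptive {_fmt(sub.pct_nonadaptive)}"
        )
    return "\n".join(lines)


@dataclass
class ClusteringReport:
    """Within-study pattern homogeneity versus a permutation null."""

    statistic: float  # mean per-study modal-category proportion
    p_value: float
    permutations: int
    seed: int | None
    null_mean: float
    null_quantiles: Mapping[float, float]
    n_studies: int
    n_blocks: int


def within_study_clustering_test(
    labels: Sequence[BlockClassification],
    permutations: int = 10000,
    seed: int | None = None,
) -> ClusteringReport:
    """Permutation test for clustering of patterns within studies.

    The statistic is the mean, over studies contributing at least two
    classified blocks, of the proportion of a study's blocks sharing the
    study's modal category.  The null shuffles category labels across
    those blocks while preserving per-study block counts; the p-value is
    the fraction of permuted statistics >= the observed one.
    """
    groups: dict[str, list[Pattern]] = {}
    for c in labels:
        if c.category is not Pattern.UNCLASSIFIED:
            groups.setdefault(c.study_id, []).append(c.category)
    sizes = [len(v) for v in groups.values() if len(v) >= 2]
    if len(sizes) < 2:
        raise ValueError("clustering test needs >= 2 studies with >= 2 classified blocks")

    cats = [v for v in groups.values() if len(v) >= 2]
    codes = {p: i for i, p in enumerate(Pattern)}
    flat = np.array([codes[p] for study in cats for p in study])
    bounds = np.cumsum([0] + sizes)

    def statistic(arr: np.ndarray) -> float:
        props = []
        for i in range(len(sizes)):
            chunk = arr[bounds[i] : bounds[i + 1]]
            props.append(np.bincount(chunk).max() / chunk.size)
        return float(np.mean(props))

    observed = statistic(flat)
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    work = flat.copy()
    for r in range(permutations):
        rng.shuffle(work)
        null[r] = statistic(work)

    qs = {q: float(np.quantile(null, q)) for q in (0.05, 0.5, 0.95)}
    return ClusteringReport(
        statistic=observed,
        p_value=float(np.mean(null >= observed)),
        permutations=permutations,
        seed=seed,
        null_mean=float(null.mean()),
        null_quantiles=qs,
        n_studies=len(sizes),
        n_blocks=int(flat.size),
    )
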