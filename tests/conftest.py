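"""Shared fixtures: random blocks, CSV builders, fake classifications."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenoplast import (
    BlockClassification,
    CellMeasure,
    PairClass,
    Pattern,
    PatternLabel,
    ScoreMode,
    Subtype,
    TraitBlock,
)
from phenoplast.records import CELL_KEYS, REQUIRED_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


def make_block(
    means,
    study_id="S001",
    trait_name="trait_01",
    trait_category="life_history",
    se=0.1,
    n=10,
):
    """Block from four cell means in canonical order (AinA, AinB, BinB, BinA)."""
    cells = {
        key: CellMeasure(float(m), se, "SE", n) for key, m in zip(CELL_KEYS, means)
    }
    return TraitBlock(study_id, trait_name, trait_category, cells)


def random_blocks(rng, n, low=-20.0, high=20.0):
    """Blocks with iid uniform cell means — sign-diverse, never exactly tied."""
    return [
        make_block(rng.uniform(low, high, size=4), study_id=f"S{i:04d}")
        for i in range(n)
    ]


def rows_for_block(means, study_id="S001", trait_name="t1", category="life_history", n=12):
    keys = ["AinA", "AinB", "BinB", "BinA"]
    return [
        {
            "study_id": study_id,
            "trait_name": trait_name,
            "trait_category": category,
            "population": k[0],
            "environment": k[-1],
            "mean": m,
            "dispersion_value": 0.5,
            "dispersion_kind": "SE",
            "n": n,
        }
        for k, m in zip(keys, means)
    ]


def write_csv(path, rows):
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)
    return path


def fake_classification(study_id, category, theta=0.53, trait_category="life_history"):
    """Minimal classification carrying only what the reporting layer reads."""
    block = make_block([10.0, 9.0, 10.0, 11.0], study_id=study_id,
                       trait_category=trait_category)
    category = Pattern(category)
    label = PatternLabel(
        category,
        Subtype.STEEP if category is Pattern.NONADAPTIVE else Subtype.NONE,
    )
    return BlockClassification(
        block=block,
        theta=theta,
        score_mode=ScoreMode.PAIR_MAX,
        pair_class_a=PairClass.NOT_PLASTIC,
        pair_class_b=PairClass.NOT_PLASTIC,
        label=label,
        subtype_a=Subtype.NONE,
        subtype_b=Subtype.NONE,
        metrics={},
        score=None,
    )
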