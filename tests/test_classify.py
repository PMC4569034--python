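"""Threshold derivation and the five-pattern decision tree."""

import pytest

from phenoplast import (
    PairClass,
    PairedRecord,
    Pattern,
    ScoreMode,
    Subtype,
    Threshold,
    classify_block,
    classify_blocks,
    classify_nonadaptive_subtype,
    classify_pair,
    derive_threshold,
    generate_block,
    ScenarioSpec,
)
from phenoplast.records import CellMeasure

from conftest import make_block, random_blocks
from helpers import naive_classify


def cell(mean, sd=1.0, n=16):
    return CellMeasure(mean, sd, "SD", n)


class TestDeriveThreshold:
    def test_mean_cv_of_two_cells(self):
        # CVs 0.4 (SD 4, mean 10) and 0.6 (SD 3, mean 5)
        block = make_block([10, 5, 10, 5])
        block = block.__class__(
            block.study_id,
            block.trait_name,
            block.trait_category,
            {
                "AinA": cell(10, 4.0),
                "AinB": cell(5, 3.0),
                "BinB": cell(10, 4.0),
                "BinA": cell(5, 3.0),
            },
        )
        assert derive_threshold([block]).theta == pytest.approx(0.5)

    def test_single_cell_cv(self):
        block = make_block([2, 2, 2, 2])
        block = block.__class__(
            block.study_id, block.trait_name, block.trait_category,
            {k: cell(2, 1.0) for k in ("AinA", "AinB", "BinB", "BinA")},
        )
        assert derive_threshold([block]).theta == pytest.approx(0.5)

    def test_constant_cv_recovered(self):
        blocks = [
            make_block([m, m + 1, m + 2, m + 3], se=0.0)
            for m in (5.0, 10.0)
        ]
        forced = []
        for b in blocks:
            cells = {
                k: CellMeasure(c.mean, 0.53 * abs(c.mean), "SD", c.n)
                for k, c in b.cells.items()
            }
            forced.append(b.__class__(b.study_id, b.trait_name, b.trait_category, cells))
        assert derive_threshold(forced).theta == pytest.approx(0.53)

    def test_zero_mean_cell_excluded_with_warning(self):
        b = make_block([0.0, 1.0, 2.0, 4.0], se=0.5)
        with pytest.warns(UserWarning, match="zero-mean"):
            theta = derive_threshold([b]).theta
        # remaining CVs: sd/|mean| with sd = 0.5*sqrt(10)
        sd = 0.5 * 10 ** 0.5
        assert theta == pytest.approx((sd / 1 + sd / 2 + sd / 4) / 3)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            derive_threshold([])


class TestClassifyPair:
    def make_pair(self, resident, nonresident):
        return PairedRecord("b", "A", cell(resident), cell(nonresident))

    @pytest.mark.parametrize(
        "resident,nonresident,expected",
        [(10, 5, PairClass.NOT_PLASTIC), (10, 4, PairClass.PLASTIC)],
    )
    def test_threshold_comparison(self, resident, nonresident, expected):
        assert classify_pair(self.make_pair(resident, nonresident), 0.53) is expected

    def test_tie_goes_to_not_plastic(self):
        pair = self.make_pair(1.0, 0.47)
        theta = abs(1.0 - 0.47) / 1.0  # exactly the metric value
        assert classify_pair(pair, theta) is PairClass.NOT_PLASTIC

    def test_degenerate_pair_unclassified(self):
        assert classify_pair(self.make_pair(0.0, 1.0), 0.53) is PairClass.UNCLASSIFIED


class TestDecisionTree:
    def test_all_cells_equal_is_canalized_no_diff(self):
        c = classify_block(make_block([10, 10, 10, 10]))
        assert c.category is Pattern.CANALIZED_NO_DIFF

    def test_differentiated_nonplastic_block(self):
        # tiny plastic responses, resident means far apart
        c = classify_block(make_block([10, 10.1, 5, 5.1]))
        assert c.category is Pattern.CANALIZED_DIFF

    def test_mixed_block_one_pair_plastic_goes_to_nonplastic_branch(self):
        # pair A strongly plastic, pair B not: never a plastic block
        c = classify_block(make_block([10, 2, 5, 5.2]))
        assert c.pair_class_a is PairClass.PLASTIC
        assert c.pair_class_b is PairClass.NOT_PLASTIC
        assert c.category in (Pattern.CANALIZED_NO_DIFF, Pattern.CANALIZED_DIFF)

    @pytest.mark.parametrize(
        "scenario,expected,subtype",
        [
            ("canalized_no_diff", Pattern.CANALIZED_NO_DIFF, Subtype.NONE),
            ("canalized_diff", Pattern.CANALIZED_DIFF, Subtype.NONE),
            ("perfect_adaptive", Pattern.PERFECT_ADAPTIVE, Subtype.NONE),
            ("adaptive", Pattern.ADAPTIVE, Subtype.NONE),
            ("nonadaptive_steep", Pattern.NONADAPTIVE, Subtype.STEEP),
            ("nonadaptive_wrong_sign", Pattern.NONADAPTIVE, Subtype.WRONG_SIGN),
        ],
    )
    @pytest.mark.parametrize("mode", [ScoreMode.PAIR_MAX, ScoreMode.BLOCK])
    def test_noise_free_scenarios_both_score_modes(self, scenario, expected, subtype, mode):
        block, _ = generate_block(ScenarioSpec(scenario, noise_cv=0.0), seed=0)
        c = classify_block(block, score_mode=mode)
        assert c.category is expected
        assert c.label.subtype is subtype

    def test_degenerate_adaptiveness_unclassified(self):
        # both pairs plastic but identical resident means
        c = classify_block(make_block([10, 2, 10, 2]))
        assert c.category is Pattern.UNCLASSIFIED

    def test_zero_resident_mean_unclassified(self):
        c = classify_block(make_block([0.0, 2.0, 5.0, 1.0]))
        assert c.category is Pattern.UNCLASSIFIED


class TestSubtype:
    @pytest.mark.parametrize(
        "aina,ainb,binb,expected",
        [
            (10, 5, 6, Subtype.STEEP),  # overshoots below the optimum
            (10, 12, 6, Subtype.WRONG_SIGN),  # moves away, above own resident
            (4, 3, 6, Subtype.WRONG_SIGN),  # moves away, below own resident
            (4, 9, 6, Subtype.STEEP),
        ],
    )
    def test_population_a_conditions(self, aina, ainb, binb, expected):
        block = make_block([aina, ainb, binb, aina])
        assert classify_nonadaptive_subtype(block, "A") is expected

    def test_population_b_mirrors(self):
        # pop B: BinB=6 < AinA=10, BinA=12 overshoots above AinA -> steep
        block = make_block([10, 10, 6, 12])
        assert classify_nonadaptive_subtype(block, "B") is Subtype.STEEP
        # BinA=4 below own resident BinB -> wrong sign
        block = make_block([10, 10, 6, 4])
        assert classify_nonadaptive_subtype(block, "B") is Subtype.WRONG_SIGN

    def test_interior_configuration_violates_precondition(self):
        # AinB strictly between the resident means: adaptiveness < 1,
        # outside the subtype rule's domain
        block = make_block([10, 8, 6, 10])
        with pytest.raises(AssertionError):
            classify_nonadaptive_subtype(block, "A")


class TestProperties:
    def test_exhaustive_and_exclusive(self, rng):
        five = {
            Pattern.CANALIZED_NO_DIFF,
            Pattern.CANALIZED_DIFF,
            Pattern.PERFECT_ADAPTIVE,
            Pattern.ADAPTIVE,
            Pattern.NONADAPTIVE,
        }
        for c in classify_blocks(random_blocks(rng, 300)):
            assert c.category in five  # uniform draws are never degenerate

    def test_plastic_set_shrinks_as_theta_grows(self, rng):
        blocks = random_blocks(rng, 200)
        previous = None
        for theta in (0.2, 0.53, 1.0, 2.0):
            plastic = {
                c.block.block_id
                for c in classify_blocks(blocks, theta)
                if c.pair_class_a is PairClass.PLASTIC
                and c.pair_class_b is PairClass.PLASTIC
            }
            if previous is not None:
                assert plastic <= previous
            previous = plastic

    def test_relabeling_invariance(self, rng):
        for block in random_blocks(rng, 200):
            aina, ainb, binb, bina = block.means
            swapped = make_block((binb, bina, aina, ainb))
            c1, c2 = classify_block(block), classify_block(swapped)
            assert c1.category is c2.category
            assert c1.subtype_a is c2.subtype_b and c1.subtype_b is c2.subtype_a
            assert c1.label.subtype is c2.label.subtype

    @pytest.mark.parametrize("c", [-3.0, 0.01, 7.0])
    def test_scale_invariance_of_labels(self, rng, c):
        for block in random_blocks(rng, 100):
            scaled = make_block([c * m for m in block.means])
            r1, r2 = classify_block(block), classify_block(scaled)
            assert r1.category is r2.category
            assert r1.label.subtype is r2.label.subtype

    def test_score_modes_coincide_under_common_standardizer(self, rng):
        for block in random_blocks(rng, 200):
            a = classify_block(block, score_mode=ScoreMode.PAIR_MAX)
            b = classify_block(block, score_mode=ScoreMode.BLOCK)
            assert a.category is b.category
            if a.score is not None:
                assert a.score == pytest.approx(b.score)

    def test_agrees_with_straight_line_oracle(self, rng):
        for theta in (0.265, 0.53, 1.06):
            for block in random_blocks(rng, 150):
                got = classify_block(block, theta)
                cat, sub, sub_a, sub_b = naive_classify(*block.means, theta)
                assert got.category.value == cat
                if cat == "nonadaptive":
                    assert (got.label.subtype.value, got.subtype_a.value,
                            got.subtype_b.value) == (sub, sub_a, sub_b)


def test_threshold_must_be_positive():
    with pytest.raises(ValueError):
        Threshold(0.0)
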