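import numpy as np
import pytest

from hypoximap import (
    HypoxiaRule,
    ParameterMaps,
    classify_voxels,
    hf_curve,
    hypoxic_fraction,
)
from hypoximap.classify import HYPOXIC, NORMOXIC, OUTSIDE_ROI, UNPHYSIOLOGICAL

from oracles import brute_force_hf


def _maps(kt, ve, roi=None):
    kt = np.asarray(kt, dtype=float)
    ve = np.asarray(ve, dtype=float)
    if roi is None:
        roi = np.ones(kt.shape, dtype=bool)
    return ParameterMaps(ktrans=kt, ve=ve, roi=roi)


class TestClassification:
    def test_ktrans_only_below_threshold_is_hypoxic(self):
        maps = _maps([[0.010]], [[0.2]])
        img = classify_voxels(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert img.labels[0, 0] == HYPOXIC

    def test_weighted_sum_boundary_arithmetic(self):
        # 0.0149/0.015 + 0.5/8.0 = 1.0558 >= 1 -> normoxic
        maps = _maps([[0.0149]], [[0.5]])
        img = classify_voxels(maps, HypoxiaRule("weighted_sum", k0trans=0.015, ve0=8.0))
        assert img.labels[0, 0] == NORMOXIC

    @pytest.mark.parametrize(
        "rule",
        [
            HypoxiaRule("ktrans_only", k0trans=0.015),
            HypoxiaRule("ve_only", ve0=0.4),
            HypoxiaRule("conjunction", k0trans=0.015, ve0=0.4),
            HypoxiaRule("weighted_sum", k0trans=0.015, ve0=8.0),
        ],
    )
    def test_ve_above_one_is_unphysiological_never_hypoxic(self, rule):
        maps = _maps([[0.001]], [[1.2]])
        img = classify_voxels(maps, rule)
        assert img.labels[0, 0] == UNPHYSIOLOGICAL

    def test_voxel_exactly_at_threshold_is_normoxic(self):
        maps = _maps([[0.015]], [[0.4]])
        img = classify_voxels(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert img.labels[0, 0] == NORMOXIC

    def test_ve_exactly_one_is_classifiable(self):
        maps = _maps([[0.01]], [[1.0]])
        img = classify_voxels(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert img.labels[0, 0] == HYPOXIC

    def test_non_finite_inside_roi_is_unphysiological(self):
        maps = _maps([[np.nan, 0.01]], [[0.3, 0.3]])
        img = classify_voxels(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert img.labels[0, 0] == UNPHYSIOLOGICAL
        assert img.labels[0, 1] == HYPOXIC

    def test_outside_roi_labelled(self):
        maps = _maps([[0.01, 0.01]], [[0.3, 0.3]], roi=np.array([[True, False]]))
        img = classify_voxels(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert img.labels[0, 1] == OUTSIDE_ROI

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError):
            HypoxiaRule("conjunction", k0trans=0.015)
        with pytest.raises(ValueError):
            HypoxiaRule("ktrans_only")


class TestHypoxicFraction:
    def test_four_voxel_worked_example(self):
        maps = _maps([0.01, 0.02, 0.03, 0.01], [0.3, 0.3, 0.3, 0.3])
        hf = hypoxic_fraction(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert hf == pytest.approx(0.5)

    def test_all_hypoxic_gives_one(self):
        maps = _maps([0.001, 0.002], [0.3, 0.3])
        assert hypoxic_fraction(maps, HypoxiaRule("ktrans_only", k0trans=0.015)) == 1.0

    def test_unphysiological_voxel_excluded_from_both_counts(self):
        maps = _maps([0.01, 0.02, 0.03, 0.01, 0.001], [0.3, 0.3, 0.3, 0.3, 1.5])
        hf = hypoxic_fraction(maps, HypoxiaRule("ktrans_only", k0trans=0.015))
        assert hf == pytest.approx(0.5)

    def test_include_unphysiological_switch_changes_denominator(self):
        maps = _maps([0.01, 0.02, 0.03, 0.01, 0.001], [0.3, 0.3, 0.3, 0.3, 1.5])
        rule = HypoxiaRule("ktrans_only", k0trans=0.015)
        assert hypoxic_fraction(maps, rule, include_unphysiological=True) == pytest.approx(0.4)

    def test_no_classifiable_voxel_is_an_error_not_zero(self):
        maps = _maps([[0.01]], [[1.5]])
        with pytest.raises(ValueError):
            hypoxic_fraction(maps, HypoxiaRule("ktrans_only", k0trans=0.015))

    @pytest.mark.parametrize(
        "rule",
        [
            HypoxiaRule("ktrans_only", k0trans=0.02),
            HypoxiaRule("ve_only", ve0=0.3),
            HypoxiaRule("conjunction", k0trans=0.02, ve0=0.3),
            HypoxiaRule("weighted_sum", k0trans=0.02, ve0=0.6),
        ],
    )
    def test_matches_brute_force_count_on_random_maps(self, rule, rng):
        for _ in range(5):
            kt = rng.uniform(0.0, 0.05, (10, 10))
            ve = rng.uniform(0.0, 1.2, (10, 10))
            maps = _maps(kt, ve)
            assert hypoxic_fraction(maps, rule) == pytest.approx(
                brute_force_hf(kt, ve, rule)
            )


class TestStrategyStructure:
    @pytest.fixture
    def random_maps(self, rng):
        kt = rng.uniform(0.0, 0.05, (12, 12))
        ve = rng.uniform(0.0, 1.1, (12, 12))
        return _maps(kt, ve)

    def test_hf_monotone_in_thresholds(self, random_maps):
        k0s = np.linspace(0.002, 0.05, 15)
        ve0s = np.linspace(0.05, 1.0, 15)
        for strat, axis in (("ktrans_only", "k"), ("ve_only", "v")):
            hfs = [
                hypoxic_fraction(
                    random_maps,
                    HypoxiaRule(strat, k0trans=k if axis == "k" else None,
                                ve0=v if axis == "v" else None),
                )
                for k, v in zip(k0s, ve0s)
            ]
            assert np.all(np.diff(hfs) >= 0)
        for strat in ("conjunction", "weighted_sum"):
            hfs_k = [
                hypoxic_fraction(random_maps, HypoxiaRule(strat, k0trans=k, ve0=0.5))
                for k in k0s
            ]
            hfs_v = [
                hypoxic_fraction(random_maps, HypoxiaRule(strat, k0trans=0.02, ve0=v))
                for v in ve0s
            ]
            assert np.all(np.diff(hfs_k) >= 0)
            assert np.all(np.diff(hfs_v) >= 0)

    def test_strategy_nesting_at_equal_thresholds(self, random_maps):
        k0, v0 = 0.02, 0.4
        hyp = {
            s: classify_voxels(
                random_maps, HypoxiaRule(s, k0trans=k0, ve0=v0)
            ).labels == HYPOXIC
            for s in ("conjunction", "weighted_sum")
        }
        hyp_i = classify_voxels(
            random_maps, HypoxiaRule("ktrans_only", k0trans=k0)
        ).labels == HYPOXIC
        hyp_ii = classify_voxels(random_maps, HypoxiaRule("ve_only", ve0=v0)).labels == HYPOXIC
        assert np.all(hyp["conjunction"] <= hyp_i)
        assert np.all(hyp["conjunction"] <= hyp_ii)
        assert np.all(hyp["weighted_sum"] <= hyp["conjunction"])

    def test_conjunction_equals_ktrans_only_when_ve0_exceeds_all_ve(self, random_maps):
        rule_iii = HypoxiaRule("conjunction", k0trans=0.02, ve0=5.0)
        rule_i = HypoxiaRule("ktrans_only", k0trans=0.02)
        assert hypoxic_fraction(random_maps, rule_iii) == hypoxic_fraction(
            random_maps, rule_i
        )

    def test_weighted_sum_converges_to_ktrans_only_as_ve0_grows(self, random_maps):
        rule_i = HypoxiaRule("ktrans_only", k0trans=0.02)
        hf_i = hypoxic_fraction(random_maps, rule_i)
        diffs = [
            abs(
                hypoxic_fraction(
                    random_maps, HypoxiaRule("weighted_sum", k0trans=0.02, ve0=v0)
                )
                - hf_i
            )
            for v0 in (10.0, 100.0, 1e4, 1e8)
        ]
        assert np.all(np.diff(diffs) <= 0)
        assert diffs[-1] == 0.0


class TestHfCurve:
    @pytest.mark.parametrize(
        "strategy, ve0",
        [("ktrans_only", None), ("conjunction", 0.4), ("weighted_sum", 0.8)],
    )
    def test_vectorized_curve_matches_per_threshold_classification(
        self, strategy, ve0, rng
    ):
        kt = rng.uniform(0.0, 0.05, 200)
        ve = rng.uniform(0.0, 1.0, 200)
        grid = np.linspace(0.002, 0.06, 25)
        curve = hf_curve(kt, ve, strategy, grid, ve0=ve0)
        for j, k0 in enumerate(grid):
            rule = HypoxiaRule(strategy, k0trans=k0, ve0=ve0)
            assert curve[j] == pytest.approx(brute_force_hf(kt, ve, rule))

    def test_ve_only_axis(self, rng):
        kt = rng.uniform(0.0, 0.05, 100)
        ve = rng.uniform(0.0, 1.0, 100)
        grid = np.linspace(0.1, 0.9, 9)
        curve = hf_curve(kt, ve, "ve_only", grid)
        for j, v0 in enumerate(grid):
            assert curve[j] == pytest.approx(
                brute_force_hf(kt, ve, HypoxiaRule("ve_only", ve0=v0))
            )
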