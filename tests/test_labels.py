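import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lisakit as lk
from lisakit.inference import PermutationResult
from lisakit.labels import LEGAL_LABELS


def make_result(pseudo_p=0.01, tail="upper", observed=1.0, sd=1.0):
    return PermutationResult(
        observed=observed,
        permuted=np.array([0.0, 1.0]),
        n_perm=999,
        pseudo_p=pseudo_p,
        tail=tail,
        standardized=float("nan") if sd == 0 else (observed - 0.5) / sd,
        lower_bound=-1.0,
        upper_bound=1.0,
        significant=pseudo_p <= 0.05 and sd > 0,
    )


class TestLocalMoran:
    @pytest.mark.parametrize(
        "z,lag,expected",
        [
            (1.2, 0.8, "high-high"),
            (-0.7, -0.3, "low-low"),
            (1.0, -0.5, "high-low"),
            (-1.0, 0.5, "low-high"),
        ],
    )
    def test_significant_quadrants(self, z, lag, expected):
        assert lk.label_local_moran(make_result(), z, lag, 0.05) == expected

    def test_not_significant(self):
        assert lk.label_local_moran(make_result(pseudo_p=0.40), 1.0, 1.0, 0.05) == "not-significant"

    def test_undefined_statistic(self):
        assert lk.label_local_moran(None, 1.0, 1.0, 0.05) == "undefined"
        assert lk.label_local_moran(make_result(), 1.0, float("nan"), 0.05) == "undefined"

    def test_zero_product_tie_breaks_to_cluster(self):
        assert lk.label_local_moran(make_result(), 0.0, 1.0, 0.05) == "high-high"
        assert lk.label_local_moran(make_result(), -1.0, 0.0, 0.05) == "low-low"


class TestLocalGeary:
    def test_positive_sa_quadrants(self):
        assert lk.label_local_geary(make_result(tail="lower"), 0.9, 1.1, 0.05) == "high-high"
        assert lk.label_local_geary(make_result(tail="lower"), -0.9, -1.1, 0.05) == "low-low"

    def test_mixed_signs_other_positive(self):
        assert lk.label_local_geary(make_result(tail="lower"), 0.9, -0.1, 0.05) == "other-positive"

    def test_upper_tail_negative_sa(self):
        assert lk.label_local_geary(make_result(tail="upper"), 0.9, 1.1, 0.05) == "negative"

    def test_not_significant(self):
        assert lk.label_local_geary(make_result(pseudo_p=0.2, tail="lower"), 1, 1, 0.05) == "not-significant"


class TestGetis:
    def test_hot_and_cold(self):
        assert lk.label_getis(make_result(pseudo_p=0.004, tail="upper"), 0.05) == "hot-spot"
        assert lk.label_getis(make_result(pseudo_p=0.004, tail="lower"), 0.05) == "cold-spot"

    def test_not_significant_and_undefined(self):
        assert lk.label_getis(make_result(pseudo_p=0.31), 0.05) == "not-significant"
        assert lk.label_getis(None, 0.05) == "undefined"

    def test_degenerate_null_never_significant(self):
        assert lk.label_getis(make_result(pseudo_p=0.001, sd=0), 0.05) == "not-significant"


class TestGlobalLabels:
    @pytest.mark.parametrize(
        "method,tail,expected",
        [
            ("moran", "upper", "positive"),
            ("moran", "lower", "negative"),
            ("geary", "lower", "positive"),
            ("geary", "upper", "negative"),
            ("general_g", "upper", "high-clustering"),
            ("general_g", "lower", "low-clustering"),
        ],
    )
    def test_significant_directions(self, method, tail, expected):
        assert lk.label_global(method, make_result(tail=tail), 0.05) == expected

    def test_not_significant(self):
        assert lk.label_global("moran", make_result(pseudo_p=0.5), 0.05) == "not-significant"


class TestLabelSets:
    def test_every_reachable_label_is_legal(self):
        """All four labelers only ever emit labels from their legal sets."""
        results = [None] + [
            make_result(pseudo_p=p, tail=t, sd=sd)
            for p in (0.01, 0.4)
            for t in ("upper", "lower")
            for sd in (1.0, 0)
        ]
        signs = (-1.3, 0.0, 1.3, float("nan"))
        for res in results:
            for z, lag in itertools.product(signs, signs):
                assert lk.label_local("local_moran", res, z, lag, 0.05) in LEGAL_LABELS["local_moran"]
                assert lk.label_local("local_geary", res, z, lag, 0.05) in LEGAL_LABELS["local_geary"]
                assert lk.label_local("gi", res, z, lag, 0.05) in LEGAL_LABELS["gi"]
                assert lk.label_local("gi_star", res, z, lag, 0.05) in LEGAL_LABELS["gi_star"]


class TestAggregate:
    def test_unanimous_high(self):
        agg = lk.aggregate_labels(["high-high", "hot-spot", "high-high"])
        assert agg.category == "high" and agg.agreement == 1.0 and agg.n_methods == 3

    def test_contradiction_high_vs_low(self):
        agg = lk.aggregate_labels(["high-high", "cold-spot", "not-significant"])
        assert agg.category == "contradiction"
        assert math.isnan(agg.agreement)

    def test_all_not_significant(self):
        agg = lk.aggregate_labels(["not-significant"] * 3)
        assert agg.category == "none" and agg.agreement == 0.0

    def test_all_undefined(self):
        agg = lk.aggregate_labels(["undefined", "undefined"])
        assert agg.category == "undefined" and agg.n_methods == 0

    def test_partial_support_fraction(self):
        agg = lk.aggregate_labels(["high-high", "not-significant", "not-significant"])
        assert agg.category == "high" and agg.agreement == pytest.approx(1 / 3)

    def test_other_positive_does_not_block_high(self):
        agg = lk.aggregate_labels(["high-high", "other-positive"])
        assert agg.category == "high" and agg.agreement == 0.5

    def test_negative_with_outlier_is_outlier_category(self):
        agg = lk.aggregate_labels(["high-low", "negative"])
        assert agg.category == "outlier" and agg.agreement == 0.5

    def test_cluster_plus_outlier_is_mixed(self):
        agg = lk.aggregate_labels(["high-high", "low-high"])
        assert agg.category == "mixed"

    def test_only_unspecific_significant_labels_is_mixed(self):
        agg = lk.aggregate_labels(["other-positive", "not-significant"])
        assert agg.category == "mixed"

    def test_undefined_excluded_from_denominator(self):
        agg = lk.aggregate_labels(["hot-spot", "undefined"])
        assert agg.category == "high" and agg.agreement == 1.0 and agg.n_methods == 1

    @given(
        st.lists(
            st.sampled_from(
                ["high-high", "low-low", "high-low", "low-high", "hot-spot",
                 "cold-spot", "other-positive", "negative", "not-significant", "undefined"]
            ),
            min_size=1,
            max_size=4,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, labels, rnd):
        before = lk.aggregate_labels(labels)
        shuffled = labels[:]
        rnd.shuffle(shuffled)
        after = lk.aggregate_labels(shuffled)
        assert before.category == after.category
        assert (before.agreement == after.agreement) or (
            math.isnan(before.agreement) and math.isnan(after.agreement)
        )

    def test_agreement_is_rational_over_defined_methods(self):
        for labels in itertools.product(
            ["high-high", "not-significant", "hot-spot"], repeat=3
        ):
            agg = lk.aggregate_labels(labels)
            if agg.category in ("high", "low", "outlier"):
                assert round(agg.agreement * agg.n_methods, 9) == int(
                    round(agg.agreement * agg.n_methods)
                )
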