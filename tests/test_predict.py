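import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readdist.predict import (ConfusionCounts, confusion_at, cross_validate,
                              pearson_matrix, percentile_vector, roc_curve,
                              train)
from readdist.predict import apply as apply_predictor

from conftest import build_sample
import oracles


class TestPercentileVector:
    def test_equally_spaced_sample_reproduces_itself(self):
        values = np.arange(1, 101) / 100.0
        got = percentile_vector(values, m=100)
        assert np.allclose(got, values)

    def test_constant_input(self):
        assert np.all(percentile_vector([0.3] * 17) == 0.3)

    def test_length_and_monotonicity(self):
        rng = np.random.default_rng(0)
        v = percentile_vector(rng.random(537))
        assert v.shape == (100,)
        assert np.all(np.diff(v) >= 0)

    def test_nearest_rank_against_direct_computation(self):
        rng = np.random.default_rng(1)
        values = rng.random(83)
        v = percentile_vector(values, m=100)
        s = np.sort(values)
        for i in range(1, 101):
            assert v[i - 1] == s[math.ceil(i * 83 / 100) - 1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            percentile_vector([])


SIX_D1 = [0.1, 0.2, 0.4, 0.6, 0.8, 1.0]
SIX_D2 = [0.2, 0.1, 0.5, 0.9, 0.7, 1.0]


class TestConfusion:
    def test_hand_enumerated_six_pair_sample(self):
        sample = build_sample(SIX_D1, SIX_D2)
        # positives: d1 in {0.1,0.2,0.4}; their d2 are 0.2,0.1,0.5, all
        # <= 0.7; among negatives only d2=0.7 slips under the threshold
        c = confusion_at(sample, "bt", "af", alpha=0.5, beta=0.7)
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 0, 2, 1)
        c = confusion_at(sample, "bt", "af", alpha=0.5, beta=0.6)
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 0, 3, 0)

    def test_perfect_predictor_has_no_errors(self):
        sample = build_sample(SIX_D1, SIX_D1)
        c = confusion_at(sample, "bt", "af", alpha=0.4, beta=0.4)
        assert c.fp == c.fn == 0

    def test_degenerate_threshold_predicts_everything_positive(self):
        sample = build_sample(SIX_D1, SIX_D2)
        c = confusion_at(sample, "bt", "af", alpha=0.5, beta=1.0)
        assert c.fn == c.tn == 0

    def test_counts_partition_the_sample(self):
        sample = build_sample(SIX_D1, SIX_D2)
        c = confusion_at(sample, "bt", "af", alpha=0.37, beta=0.62)
        assert c.total == 6

    def test_missing_distance_lists_offenders(self):
        sample = build_sample(SIX_D1, SIX_D2)
        with pytest.raises(ValueError, match="nw"):
            confusion_at(sample, "bt", "nw", 0.5, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=60)
    def test_positive_count_independent_of_beta(self, alpha, beta):
        sample = build_sample(SIX_D1, SIX_D2)
        c = confusion_at(sample, "bt", "af", alpha, beta)
        assert c.tp + c.fn == sum(d <= alpha for d in SIX_D1)
        assert c.tn + c.fp == sum(d > alpha for d in SIX_D1)

    def test_rates_monotone_in_beta(self):
        sample = build_sample(SIX_D1, SIX_D2)
        betas = np.linspace(0, 1, 21)
        tprs, fprs = [], []
        for b in betas:
            c = confusion_at(sample, "bt", "af", 0.5, b)
            tprs.append(c.tp_rate)
            fprs.append(1 - c.tn_rate)
        assert np.all(np.diff(tprs) >= 0)
        assert np.all(np.diff(fprs) >= 0)


class TestROC:
    def test_perfect_predictor_auc_is_one(self):
        sample = build_sample(SIX_D1, SIX_D1)
        curve = roc_curve(sample, "bt", "af", alpha=0.5,
                          candidate_betas=sorted(SIX_D1))
        assert curve.auc == 1.0

    def test_six_pair_curve_matches_hand_computation(self):
        sample = build_sample(SIX_D1, SIX_D2)
        curve = roc_curve(sample, "bt", "af", alpha=0.5,
                          candidate_betas=sorted(SIX_D2))
        # positives: d1<=0.5 -> pairs 0,1,2 (d2=0.2,0.1,0.5); negatives
        # d2=0.9,0.7,1.0. Every candidate beta < 0.7 has fpr 0.
        assert (0.0, 1.0) in curve.points
        assert curve.auc == 1.0

    def test_independent_predictor_auc_near_half(self):
        rng = np.random.default_rng(8)
        d1 = rng.random(4000)
        d2 = rng.random(4000)
        sample = build_sample(d1, d2)
        curve = roc_curve(sample, "bt", "af", alpha=0.5,
                          candidate_betas=percentile_vector(d2))
        assert abs(curve.auc - 0.5) < 0.05

    def test_points_sorted_and_anchored(self):
        sample = build_sample(SIX_D1, SIX_D2)
        curve = roc_curve(sample, "bt", "af", 0.5, sorted(SIX_D2))
        xs = [p[0] for p in curve.points]
        assert xs == sorted(xs)
        # the (0,0) anchor may merge with a candidate point at fpr=0
        assert curve.points[0][0] == 0.0
        assert curve.points[-1] == (1.0, 1.0)

    def test_alpha_outside_unit_interval_rejected(self):
        sample = build_sample(SIX_D1, SIX_D2)
        with pytest.raises(ValueError):
            roc_curve(sample, "bt", "af", 1.5, [0.5])

    def test_auc_equals_mann_whitney_with_exhaustive_betas(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = 50
            d1 = rng.random(n)
            d2 = rng.random(n)  # continuous: no cross-class ties
            alpha = float(np.quantile(d1, 0.4))
            sample = build_sample(d1, d2)
            curve = roc_curve(sample, "bt", "af", alpha,
                              candidate_betas=np.unique(d2))
            pos = d2[d1 <= alpha]
            neg = d2[d1 > alpha]
            expected = oracles.mann_whitney_auc(pos, neg)
            assert curve.auc == pytest.approx(expected, abs=1e-12)


class TestTrain:
    def test_perfect_predictor_recovers_alpha_as_beta(self):
        rng = np.random.default_rng(2)
        d1 = rng.random(500)
        predictor = train(build_sample(d1, d1), "bt", "af")
        ok = ~np.isnan(predictor.beta)  # the top level has no negatives
        assert ok.sum() >= 99
        assert np.allclose(predictor.beta[ok], predictor.alpha[ok])
        assert np.allclose(predictor.auc[ok], 1.0)

    def test_anti_predictor_auc_at_most_half(self):
        rng = np.random.default_rng(3)
        d1 = rng.random(400)
        predictor = train(build_sample(d1, 1 - d1), "bt", "af")
        defined = predictor.auc[~np.isnan(predictor.auc)]
        assert np.all(defined <= 0.5 + 1e-12)

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            train(build_sample([0.5] * 200, np.linspace(0, 1, 200)),
                  "bt", "af")

    def test_invariant_under_monotone_transform_of_predictor(self):
        rng = np.random.default_rng(4)
        d1 = rng.random(300)
        d2 = np.clip(d1 + rng.normal(0, 0.2, 300), 0, 1)
        base = train(build_sample(d1, d2), "bt", "af")
        for f in (np.sqrt, np.square, lambda x: x / (2 - x)):
            other = train(build_sample(d1, f(d2)), "bt", "af")
            assert np.allclose(base.auc, other.auc, equal_nan=True)
            # fitted beta is the transformed fitted beta
            ok = ~np.isnan(base.beta)
            assert np.allclose(other.beta[ok], f(base.beta[ok]))

    def test_simulated_af_predictor_is_strong_at_low_levels(
            self, small_subsets):
        from readdist.distances import compute_all_distances
        scored = compute_all_distances(small_subsets[0], which=("bt", "af"))
        predictor = train(scored, "bt", "af")
        assert np.nanmin(predictor.auc[9:25]) >= 0.9

    def test_auc_profile_decreases_with_level(self, small_subsets):
        from readdist.distances import compute_all_distances
        scored = compute_all_distances(small_subsets[1], which=("bt", "af"))
        predictor = train(scored, "bt", "af")
        auc = predictor.auc[~np.isnan(predictor.auc)]
        # noisy but systematic: early-level mean exceeds late-level mean
        third = len(auc) // 3
        assert auc[:third].mean() > auc[-third:].mean()


class TestApplyAndCrossval:
    def test_apply_on_training_sample_with_perfect_predictor(self):
        rng = np.random.default_rng(5)
        d1 = rng.random(300)
        sample = build_sample(d1, d1)
        predictor = train(sample, "bt", "af")
        _, tp_rate, tn_rate = apply_predictor(predictor, sample, level=40)
        assert (tp_rate, tn_rate) == (1.0, 1.0)

    def test_apply_generalizes_between_iid_samples(self, small_subsets):
        from readdist.distances import compute_all_distances
        a = compute_all_distances(small_subsets[0], which=("bt", "af"))
        b = compute_all_distances(small_subsets[1], which=("bt", "af"))
        predictor = train(a, "bt", "af")
        _, tp_a, tn_a = apply_predictor(predictor, a, level=20)
        _, tp_b, tn_b = apply_predictor(predictor, b, level=20)
        assert abs(tp_a - tp_b) < 0.1 and abs(tn_a - tn_b) < 0.1

    def test_empty_positive_class_yields_nan_rate_not_zero(self):
        rng = np.random.default_rng(6)
        d1 = rng.uniform(0.5, 1.0, 200)
        predictor = train(build_sample(d1, d1), "bt", "af")
        # evaluate on a sample with no pair below alpha_1 (~0.5)
        test = build_sample(rng.uniform(0.9, 1.0, 100),
                            rng.uniform(0.9, 1.0, 100))
        counts, tp_rate, _ = apply_predictor(predictor, test, level=1)
        assert counts.tp + counts.fn == 0
        assert math.isnan(tp_rate)

    def test_identical_samples_with_perfect_predictor_score_100(self):
        rng = np.random.default_rng(7)
        d1 = rng.random(400)
        samples = [build_sample(d1, d1, label=l) for l in "ABCDEF"]
        result = cross_validate(samples, "bt", "af",
                                reference_alphas=(0.105, 0.25))
        rates = result.table.drop(index="Average")
        assert (rates.to_numpy() == 100.0).all()

    def test_fold_structure(self, small_subsets):
        from readdist.distances import compute_all_distances
        scored = [compute_all_distances(s, which=("bt", "af"))
                  for s in small_subsets]
        result = cross_validate(scored, "bt", "af")
        assert list(result.table.index) == list("ABCDEF") + ["Average"]
        per_fold = result.records[result.records.fold == "A"].iloc[0]
        n_test = sum(len(s) for s in scored[1:])
        assert per_fold[["tp", "fp", "tn", "fn"]].sum() == n_test

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            cross_validate([build_sample(SIX_D1, SIX_D2)])


class TestPearson:
    def test_unit_diagonal_and_symmetry(self, small_subsets):
        from readdist.distances import compute_all_distances
        scored = compute_all_distances(small_subsets[2])
        mat = pearson_matrix(scored)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_anticorrelated_columns(self):
        rng = np.random.default_rng(9)
        d1 = rng.random(50)
        sample = build_sample(d1, 1 - d1)
        # fill remaining columns so the matrix is computable
        from dataclasses import replace as drep
        pairs = tuple(drep(p, nw=float(x), bl=float(1 - x))
                      for p, x in zip(sample.pairs, d1))
        sample = drep(sample, pairs=pairs)
        mat = pearson_matrix(sample)
        assert mat.loc["bt", "af"] == pytest.approx(-1.0)
        assert mat.loc["bt", "nw"] == pytest.approx(1.0)

    def test_five_pair_hand_table_matches_direct_formula(self):
        d1 = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        d2 = np.array([0.2, 0.2, 0.6, 0.5, 1.0])
        from dataclasses import replace as drep
        sample = build_sample(d1, d2)
        pairs = tuple(drep(p, nw=float(a), bl=float(b))
                      for p, a, b in zip(sample.pairs, d1, d2))
        sample = drep(sample, pairs=pairs)
        mat = pearson_matrix(sample)
        num = np.mean(d1 * d2) - d1.mean() * d2.mean()
        expected = num / (d1.std() * d2.std())
        assert mat.loc["bt", "af"] == pytest.approx(expected)

    def test_zero_variance_column_named_in_error(self):
        sample = build_sample([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
        from dataclasses import replace as drep
        pairs = tuple(drep(p, nw=float(x), bl=float(x))
                      for p, x in zip(sample.pairs, (0.2, 0.4, 0.6)))
        sample = drep(sample, pairs=pairs)
        with pytest.raises(ValueError, match="af"):
            pearson_matrix(sample)
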