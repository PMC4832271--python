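"""Threshold-averaged ROC curves, AUC, retention and train/test checks."""

import numpy as np
import pytest

from ebfine import (
    Replicate,
    RocCurve,
    auc,
    bootstrap_auc,
    retained_at_tpr,
    roc_threshold_average,
    simulate_case_control,
    train_test_web,
)


def _random_replicate(rng, m=60, causal=0, boost=0.0):
    scores = rng.normal(0, 1, m)
    scores[causal] += boost
    flags = np.zeros(m, dtype=bool)
    flags[causal] = True
    return Replicate(scores=scores, causal=flags)


class TestThresholdAveraging:
    def test_single_replicate_matches_brute_force_points(self):
        rng = np.random.default_rng(0)
        rep = _random_replicate(rng, m=100, boost=2.0)
        curve = roc_threshold_average([rep], n_thresholds=64)
        pos = rep.scores[rep.causal]
        neg = rep.scores[~rep.causal]
        for t, f, tp in zip(curve.thresholds, curve.mean_fpr, curve.mean_tpr):
            assert tp == pytest.approx(np.mean(pos >= t))
            assert f == pytest.approx(np.mean(neg >= t))

    def test_single_replicate_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 300).astype(bool)
        labels[0] = True
        labels[1] = False
        scores = rng.normal(0, 1, 300) + labels
        curve = roc_threshold_average([Replicate(scores, labels)], n_thresholds=2048)
        assert auc(curve) == pytest.approx(roc_auc_score(labels, scores), abs=0.01)

    def test_perfect_statistic_has_unit_tpr_at_positive_fpr(self):
        rng = np.random.default_rng(2)
        reps = []
        for _ in range(20):
            rep = _random_replicate(rng, boost=100.0)
            reps.append(rep)
        curve = roc_threshold_average(reps)
        assert (curve.mean_tpr[curve.mean_fpr > 0] == 1.0).all()

    def test_uninformative_scores_give_half_auc(self):
        rng = np.random.default_rng(3)
        reps = [_random_replicate(rng, boost=0.0) for _ in range(200)]
        assert auc(roc_threshold_average(reps)) == pytest.approx(0.5, abs=0.05)

    def test_replicate_without_causal_named(self):
        good = Replicate(np.arange(5.0), np.array([1, 0, 0, 0, 0], dtype=bool))
        bad = Replicate(np.arange(5.0), np.zeros(5, dtype=bool))
        with pytest.raises(ValueError, match="replicate 1"):
            roc_threshold_average([good, bad])

    def test_curve_spans_unit_square(self):
        rng = np.random.default_rng(4)
        curve = roc_threshold_average([_random_replicate(rng) for _ in range(10)])
        assert curve.mean_fpr[0] == curve.mean_tpr[0] == 0.0
        assert curve.mean_fpr[-1] == curve.mean_tpr[-1] == 1.0
        assert (np.diff(curve.mean_fpr) >= 0).all()
        assert (np.diff(curve.mean_tpr) >= 0).all()


class TestAuc:
    def test_diagonal_and_step_curves(self):
        grid = np.linspace(0, 1, 11)
        diag = RocCurve(np.linspace(1, 0, 11), grid, grid, 1)
        assert auc(diag) == pytest.approx(0.5)
        step = RocCurve(np.array([np.inf, 0.5, -np.inf]), np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]), 1)
        assert auc(step) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            auc(RocCurve(np.array([np.inf]), np.array([0.0]), np.array([0.0]), 1))

    def test_bootstrap_sd_positive_and_point_consistent(self):
        rng = np.random.default_rng(5)
        reps = [_random_replicate(rng, boost=1.5) for _ in range(40)]
        point, sd = bootstrap_auc(reps, n_boot=200, seed=1)
        assert point == pytest.approx(auc(roc_threshold_average(reps)), abs=1e-12)
        assert 0 < sd < 0.2


class TestRetention:
    def test_perfect_statistic_retains_only_causal(self):
        rng = np.random.default_rng(6)
        reps = [_random_replicate(rng, m=40, boost=100.0) for _ in range(25)]
        summary = retained_at_tpr(reps, 0.9)
        assert summary.mean_tpr >= 0.9
        # the threshold sits at a low causal score, so nearly every replicate
        # retains exactly its causal SNP and nothing else
        assert 0.9 <= summary.mean_retained <= 1.0

    def test_constant_statistic_retains_everything(self):
        flags = np.zeros(30, dtype=bool)
        flags[3] = True
        reps = [Replicate(np.ones(30), flags) for _ in range(5)]
        summary = retained_at_tpr(reps, 0.9)
        assert summary.mean_retained == 30.0

    def test_intersection_with_itself_equals_counts(self):
        rng = np.random.default_rng(7)
        reps = [_random_replicate(rng, boost=2.0) for _ in range(30)]
        summary = retained_at_tpr(reps, 0.8, secondary=reps)
        assert summary.intersection_mean == pytest.approx(summary.mean_retained)

    def test_informative_prior_shrinks_retained_set(self):
        """Posterior filtering with the causal SNP up-weighted retains fewer
        SNPs than BF filtering at the same TPR (Table-4-style contrast)."""
        rng = np.random.default_rng(8)
        bf_reps, post_reps = [], []
        delta_boost = np.log(125.0)  # group-4 vs group-1 prior odds gap, R=5
        for _ in range(60):
            rep = _random_replicate(rng, m=50, boost=1.0)
            bf_reps.append(rep)
            post = rep.scores.copy()
            post[rep.causal] += delta_boost
            post_reps.append(Replicate(post, rep.causal))
        bf_summary = retained_at_tpr(bf_reps, 0.9)
        post_summary = retained_at_tpr(post_reps, 0.9)
        assert post_summary.mean_retained < bf_summary.mean_retained

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            retained_at_tpr([_random_replicate(np.random.default_rng(0))], 0.0)


class TestTrainTest:
    def _pairs(self, panel, n_pairs, effect, seed0):
        pairs = []
        for k in range(n_pairs):
            train = simulate_case_control(panel, 20, effect, 250, 250, seed=seed0 + 2 * k)
            test = simulate_case_control(panel, 20, effect, 250, 250, seed=seed0 + 2 * k + 1)
            pairs.append((train, test))
        return pairs

    def test_identical_train_test_curves_coincide(self, small_panel):
        ds = simulate_case_control(small_panel, 20, 1.4, 300, 300, seed=31)
        same, cross = train_test_web([(ds, ds)])
        assert np.allclose(same.mean_tpr, cross.mean_tpr)
        assert np.allclose(same.mean_fpr, cross.mean_fpr)

    def test_null_effect_gives_half_auc(self, small_panel):
        pairs = self._pairs(small_panel, 12, 1.0, 500)
        same, cross = train_test_web(pairs, n_thresholds=128)
        assert auc(same) == pytest.approx(0.5, abs=0.2)
        assert auc(cross) == pytest.approx(0.5, abs=0.2)

    def test_no_overfitting_with_strong_effect(self, small_panel):
        pairs = self._pairs(small_panel, 12, 1.6, 900)
        same, cross = train_test_web(pairs, n_thresholds=128)
        assert auc(same) > 0.6
        assert abs(auc(same) - auc(cross)) < 0.1

    def test_mismatched_snp_sets_rejected(self, small_panel, small_dataset):
        from ebfine import make_haplotype_panel

        other = make_haplotype_panel(100, 10, seed=3)
        ds2 = simulate_case_control(other, 5, 1.2, 100, 100, seed=1)
        with pytest.raises(ValueError, match="different SNP"):
            train_test_web([(small_dataset, ds2)])
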