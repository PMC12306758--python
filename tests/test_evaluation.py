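"""Metrics, sliding-window stratification, and toy correlations."""

import numpy as np
import pytest
from scipy.stats import rankdata

from logituq.evaluation import (
    auprc,
    auroc,
    calibration_curve,
    curvature_profile,
    ece,
    instance_nll,
    nll,
    sliding_window_stratification,
    spearman,
    correlate_uncertainty_with,
)
from logituq.synthetic import ToyLaw


class TestDiscrimination:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert auroc(p, y) == 1.0
        assert auprc(p, y) == 1.0

    def test_chance_level(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=4000) < 0.5).astype(int)
        p = rng.uniform(size=4000)
        assert auroc(p, y) == pytest.approx(0.5, abs=0.03)

    def test_auroc_matches_pairwise_concordance(self):
        rng = np.random.default_rng(1)
        y = (rng.uniform(size=30) < 0.4).astype(int)
        p = rng.uniform(size=30)
        pos, neg = p[y == 1], p[y == 0]
        wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        assert auroc(p, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = (rng.uniform(size=50) < 0.3).astype(int)
        p = rng.uniform(size=50)
        assert auroc(np.exp(3 * p), y) == pytest.approx(auroc(p, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCalibration:
    def test_perfectly_calibrated_bins(self):
        p = np.array([0.25] * 4 + [0.75] * 4)
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        assert ece(p, y, bins=2) == 0.0

    def test_hand_binned_example(self):
        # bin1: |0.2 - 0.5| * 1/2, bin2: |0.8 - 1.0| * 1/2
        p = np.array([0.2, 0.2, 0.8, 0.8])
        y = np.array([0, 1, 1, 1])
        assert ece(p, y, bins=2) == pytest.approx(0.25)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        y = (rng.uniform(size=200) < p).astype(int)
        perm = rng.permutation(200)
        assert ece(p, y) == pytest.approx(ece(p[perm], y[perm]))

    def test_curve_reports_counts_and_omits_empty_bins(self):
        p = np.array([0.05, 0.06, 0.95])
        y = np.array([0, 0, 1])
        curve = calibration_curve(p, y, bins=10)
        assert curve["count"].sum() == 3
        assert len(curve) == 2  # only two occupied bins

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ece(np.array([1.2]), np.array([1]), bins=5)
        with pytest.raises(ValueError):
            calibration_curve(np.array([0.5]), np.array([1]), bins=0)


class TestNLL:
    def test_half_probability_gives_log_two(self):
        p = np.full(10, 0.5)
        y = (np.arange(10) % 2).astype(int)
        assert nll(p, y) == pytest.approx(np.log(2.0))

    def test_confident_correct_predictions_hit_clip_floor(self):
        p = np.array([1.0, 0.0])
        y = np.array([1, 0])
        assert nll(p, y) == pytest.approx(-np.log(1 - 1e-12), abs=1e-15)

    def test_matches_elementwise_hand_computation(self):
        p = np.array([0.9, 0.2, 0.6, 0.4, 0.07])
        y = np.array([1, 0, 0, 1, 1])
        by_hand = -np.array(
            [np.log(0.9), np.log(0.8), np.log(0.4), np.log(0.4), np.log(0.07)]
        )
        assert np.allclose(instance_nll(p, y), by_hand)
        assert nll(p, y) == pytest.approx(by_hand.mean())


def _brute_force_stratification(values, unc, window):
    order = np.argsort(unc, kind="stable")
    v = values[order]
    means = np.array([v[i : i + window].mean() for i in range(len(v) - window + 1)])
    ranks_x = rankdata(np.arange(len(means)))
    ranks_y = rankdata(means)
    rho = np.corrcoef(ranks_x, ranks_y)[0, 1]
    return means, rho


class TestStratification:
    def test_window_count(self):
        res = sliding_window_stratification(np.arange(9.0), np.arange(9.0))
        assert res.n_windows == 7  # n - w + 1 with w = 3

    def test_monotone_case_gives_spearman_one(self):
        unc = np.linspace(0, 1, 30)
        values = unc * 2 + 1
        res = sliding_window_stratification(values, unc)
        assert res.spearman == pytest.approx(1.0)

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(size=30)
        unc = rng.uniform(size=30)
        res = sliding_window_stratification(values, unc)
        means, rho = _brute_force_stratification(values, unc, 10)
        assert np.allclose(res.window_mean_nll, means)
        assert res.spearman == pytest.approx(rho)

    def test_ties_broken_by_stable_original_order(self):
        values = np.array([5.0, 1.0, 2.0, 3.0])
        unc = np.array([0.5, 0.5, 0.5, 0.1])
        res = sliding_window_stratification(values, unc, window=2)
        # order: index 3 first, then 0, 1, 2
        assert np.allclose(res.window_mean_nll, [4.0, 3.0, 1.5])

    def test_constant_uncertainty_flagged(self):
        res = sliding_window_stratification(np.arange(9.0), np.ones(9))
        assert res.constant_uncertainty
        assert res.spearman is None

    def test_sum_and_mean_spans(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(size=12)
        unc = rng.uniform(size=12)
        res = sliding_window_stratification(values, unc)
        assert res.nll_span_sum == pytest.approx(res.nll_span_mean * res.window)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sliding_window_stratification(np.arange(2.0), np.arange(2.0))
        with pytest.raises(ValueError):
            sliding_window_stratification(np.arange(9.0), np.arange(8.0))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.random.default_rng(6).uniform(size=20)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_matches_closed_form_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.permutation(10).astype(float)
            y = rng.permutation(10).astype(float)
            d = rankdata(x) - rankdata(y)
            closed = 1 - 6 * np.sum(d**2) / (10 * (100 - 1))
            assert spearman(x, y) == pytest.approx(closed)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))


class TestToyCorrelation:
    def test_self_correlation_is_one(self):
        law = ToyLaw()
        rng = np.random.default_rng(8)
        pts = rng.uniform(size=(200, 2))
        from logituq.synthetic import true_density

        rho, pairs = correlate_uncertainty_with(law, pts, true_density(law, pts), "density")
        assert rho == pytest.approx(1.0)
        assert set(pairs.columns) == {"u_epi", "density"}

    def test_independent_uncertainty_uncorrelated(self):
        law = ToyLaw()
        rng = np.random.default_rng(9)
        pts = rng.uniform(size=(3000, 2))
        rho, _ = correlate_uncertainty_with(law, pts, rng.uniform(size=3000), "label_noise")
        assert abs(rho) < 0.06

    def test_pipeline_matches_manual_spearman(self):
        from logituq.synthetic import true_label_noise

        law = ToyLaw()
        rng = np.random.default_rng(10)
        pts = rng.uniform(size=(100, 2))
        u = rng.uniform(size=100)
        rho, pairs = correlate_uncertainty_with(law, pts, u, "label_noise")
        assert rho == pytest.approx(spearman(u, true_label_noise(law, pts)))

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            correlate_uncertainty_with(ToyLaw(), np.zeros((1, 2)), np.zeros(1), "entropy")


class TestCurvature:
    def test_minimum_and_symmetry(self):
        assert curvature_profile(np.array([0.5]))[0] == pytest.approx(4.0)
        assert curvature_profile(np.array([0.2]))[0] == pytest.approx(
            curvature_profile(np.array([0.8]))[0]
        )

    def test_tail_inflation_ratio(self):
        ratio = curvature_profile(np.array([0.01]))[0] / 4.0
        assert ratio == pytest.approx(1 / (0.01 * 0.99) / 4)

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(ValueError):
            curvature_profile(np.array([0.0]))
        with pytest.raises(ValueError):
            curvature_profile(np.array([1.0]))
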