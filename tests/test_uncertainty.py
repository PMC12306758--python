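"""Logit-space uncertainty measures: Bayes factor, ES, u_tot, u_epi."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from logituq.uncertainty import (
    LogitPosterior,
    bayes_factor,
    epistemic_uncertainty,
    evidential_strength,
    prior_log_odds,
    score_instances,
    total_uncertainty,
)


class TestPriorLogOdds:
    def test_balanced_labels_give_zero(self):
        assert prior_log_odds(np.array([0, 1, 0, 1])) == 0.0

    def test_cohort_counts_example(self):
        # 536 positives vs 7128 negatives -> log(536/7128)
        labels = np.concatenate([np.ones(536), np.zeros(7128)])
        assert prior_log_odds(labels) == pytest.approx(np.log(536 / 7128))
        assert prior_log_odds(labels) == pytest.approx(-2.588, abs=5e-4)

    def test_adding_equal_counts_moves_toward_zero(self):
        for n1, n0 in [(3, 17), (40, 8), (6, 6)]:
            base = np.concatenate([np.ones(n1), np.zeros(n0)])
            grown = np.concatenate([np.ones(n1 + 10), np.zeros(n0 + 10)])
            assert abs(prior_log_odds(grown)) <= abs(prior_log_odds(base)) + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            prior_log_odds(np.ones(5))


class TestBayesFactor:
    def test_neutral_and_doubling(self):
        assert bayes_factor(np.array([-1.3]), -1.3)[0] == pytest.approx(1.0)
        assert bayes_factor(np.array([np.log(2.0)]), 0.0)[0] == pytest.approx(2.0)

    def test_log_identity(self):
        rng = np.random.default_rng(0)
        lx = rng.uniform(-5, 5, 50)
        l1 = -2.0
        assert np.allclose(np.log(bayes_factor(lx, l1)), lx - l1, atol=1e-12)


class TestEvidentialStrength:
    def test_neutral_posterior_mean(self):
        post = LogitPosterior.from_samples(np.full((3, 10), -1.7))
        assert np.allclose(evidential_strength(post, -1.7), 0.0)

    def test_symmetric_samples_around_prior(self):
        l1 = 0.4
        post = LogitPosterior.from_samples(np.array([[l1 + 2.0, l1 - 2.0]]))
        assert evidential_strength(post, l1)[0] == pytest.approx(0.0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        samples = rng.standard_normal((20, 7))
        l1 = -0.3
        es = evidential_strength(LogitPosterior.from_samples(samples), l1)
        brute = np.array([abs(np.mean(row) - l1) for row in samples])
        assert np.allclose(es, brute)


class TestTransforms:
    def test_total_uncertainty_values(self):
        assert total_uncertainty(np.array([0.0]))[0] == 1.0
        assert total_uncertainty(np.array([1e6]))[0] <= 1e-12
        assert total_uncertainty(np.array([np.log(2.0)]), k=1.0)[0] == pytest.approx(0.5)

    def test_epistemic_uncertainty_values(self):
        delta = LogitPosterior.from_samples(np.full((1, 5), 2.2))
        assert epistemic_uncertainty(delta)[0] == 0.0
        gauss0 = LogitPosterior.from_gaussian(np.array([1.0]), np.array([0.0]))
        assert epistemic_uncertainty(gauss0)[0] == 0.0
        wide = LogitPosterior.from_gaussian(np.array([0.0]), np.array([1e6]))
        assert epistemic_uncertainty(wide)[0] >= 1.0 - 1e-12
        two_point = LogitPosterior.from_samples(np.array([[0.0, 2.0]]))
        # unbiased two-point variance is 2
        assert epistemic_uncertainty(two_point)[0] == pytest.approx(1 - np.exp(-2.0))

    def test_invalid_decay_rate(self):
        with pytest.raises(ValueError):
            total_uncertainty(np.array([1.0]), k=0.0)
        with pytest.raises(ValueError):
            epistemic_uncertainty(
                LogitPosterior.from_gaussian(np.zeros(1), np.ones(1)), k=-1.0
            )

    def test_single_draw_variance_warns_and_returns_zero(self):
        post = LogitPosterior.from_samples(np.array([[1.5], [0.5]]))
        with pytest.warns(RuntimeWarning):
            assert np.allclose(post.variance(), 0.0)


class TestScoreInstances:
    def test_gaussian_form_matches_large_sample_approximation(self):
        rng = np.random.default_rng(2)
        mean = np.array([0.5, -1.0, 2.0])
        var = np.array([0.3, 1.2, 0.05])
        gauss = score_instances(LogitPosterior.from_gaussian(mean, var), l1=-0.5)
        draws = mean[:, None] + np.sqrt(var)[:, None] * rng.standard_normal((3, 100000))
        sampled = score_instances(LogitPosterior.from_samples(draws), l1=-0.5)
        assert np.allclose(gauss.es, sampled.es, atol=0.02)
        assert np.allclose(gauss.u_epi, sampled.u_epi, atol=0.02)

    def test_instance_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        samples = rng.standard_normal((12, 6))
        perm = rng.permutation(12)
        a = score_instances(LogitPosterior.from_samples(samples), 0.2)
        b = score_instances(LogitPosterior.from_samples(samples[perm]), 0.2)
        assert np.allclose(a.es[perm], b.es)
        assert np.allclose(a.u_epi[perm], b.u_epi)

    def test_doubling_k_squares_u_tot(self):
        rng = np.random.default_rng(4)
        samples = rng.standard_normal((9, 4))
        post = LogitPosterior.from_samples(samples)
        a = score_instances(post, 0.0, k=1.0)
        b = score_instances(post, 0.0, k=2.0)
        assert np.allclose(b.u_tot, a.u_tot**2)

    @settings(max_examples=40, deadline=None)
    @given(
        samples=hnp.arrays(
            float,
            (6, 5),
            elements=st.floats(-30, 30, allow_nan=False),
        ),
        l1=st.floats(-4, 4),
        k=st.floats(0.05, 5.0),
    )
    def test_class_relabeling_symmetry(self, samples, l1, k):
        # swapping class labels negates every log-odds; measures unchanged
        post = LogitPosterior.from_samples(samples)
        flipped = LogitPosterior.from_samples(-samples)
        a = score_instances(post, l1, k)
        b = score_instances(flipped, -l1, k)
        assert np.allclose(a.es, b.es, rtol=1e-9, atol=1e-9)
        assert np.allclose(a.u_tot, b.u_tot, rtol=1e-9, atol=1e-9)
        assert np.allclose(a.u_epi, b.u_epi, rtol=1e-9, atol=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(k=st.floats(0.05, 3.0), seed=st.integers(0, 2**16))
    def test_rankings_invariant_to_decay_rate(self, k, seed):
        # moderate scales keep the exponential transforms away from
        # floating-point saturation, where ranks would tie
        rng = np.random.default_rng(seed)
        post = LogitPosterior.from_samples(rng.standard_normal((15, 6)))
        base = score_instances(post, 0.3, k=1.0)
        other = score_instances(post, 0.3, k=k)
        # u_tot ranking reverses the ES ranking for any k
        assert np.array_equal(np.argsort(base.es), np.argsort(-other.u_tot))
        assert np.array_equal(np.argsort(base.u_epi), np.argsort(other.u_epi))

    def test_measure_bounds(self):
        rng = np.random.default_rng(5)
        post = LogitPosterior.from_samples(rng.standard_normal((50, 8)))
        s = score_instances(post, -2.0)
        assert np.all((s.u_tot > 0) & (s.u_tot <= 1))
        assert np.all((s.u_epi >= 0) & (s.u_epi < 1))
        assert np.all(s.es >= 0)


class TestLogitPosteriorContainer:
    def test_exactly_one_form_required(self):
        with pytest.raises(ValueError):
            LogitPosterior()
        with pytest.raises(ValueError):
            LogitPosterior(
                samples=np.zeros((2, 2)), gauss_mean=np.zeros(2), gauss_var=np.zeros(2)
            )

    def test_negative_gaussian_variance_rejected(self):
        with pytest.raises(ValueError):
            LogitPosterior.from_gaussian(np.zeros(2), np.array([0.1, -0.1]))

    def test_frame_export(self):
        post = LogitPosterior.from_samples(np.zeros((3, 2)))
        frame = score_instances(post, 0.0).to_frame()
        assert list(frame.columns) == ["es", "u_tot", "u_epi", "l1", "k"]
        assert len(frame) == 3
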