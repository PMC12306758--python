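"""Random Fourier features, Laplace covariance, and SNGP predictions."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from logituq.backbone import TrainConfig, sigmoid
from logituq.sngp import (
    RandomFourierFeatures,
    SNGPClassifier,
    laplace_precision,
    latent_to_probability,
)


class TestRandomFourierFeatures:
    def test_self_inner_product_near_one(self):
        rff = RandomFourierFeatures(3, 4096, 1.0, seed=0)
        H = np.random.default_rng(1).standard_normal((50, 3))
        phi = rff.transform(H)
        norms = np.einsum("ij,ij->i", phi, phi)
        assert np.all(np.abs(norms - 1.0) < 3 / np.sqrt(4096))

    def test_inner_products_approximate_rbf_kernel(self):
        ell = 1.4
        rff = RandomFourierFeatures(2, 4096, ell, seed=2)
        rng = np.random.default_rng(3)
        A = rng.standard_normal((30, 2))
        B = rng.standard_normal((30, 2))
        K_hat = rff.transform(A) @ rff.transform(B).T
        K = np.exp(-cdist(A, B, "sqeuclidean") / (2 * ell**2))
        err = np.abs(K_hat - K)
        # 3/sqrt(D) is a three-sigma Monte-Carlo bound per inner product
        assert np.quantile(err, 0.99) < 3 / np.sqrt(4096)
        assert err.max() < 5 / np.sqrt(4096)

    def test_frozen_projection_reproducible(self):
        a = RandomFourierFeatures(4, 64, 2.0, seed=5)
        b = RandomFourierFeatures(4, 64, 2.0, seed=5)
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.phase, b.phase)

    def test_norm_bounded_by_sqrt_two(self):
        rff = RandomFourierFeatures(2, 32, 0.5, seed=7)
        phi = rff.transform(np.random.default_rng(0).standard_normal((20, 2)))
        assert np.all(np.linalg.norm(phi, axis=1) <= np.sqrt(2.0) + 1e-12)

    def test_dimension_mismatch(self):
        rff = RandomFourierFeatures(3, 16, 1.0, seed=0)
        with pytest.raises(ValueError):
            rff.transform(np.zeros((2, 4)))


class TestLaplacePrecision:
    def test_prior_only_limit(self):
        phi = np.zeros((0, 5))
        P = laplace_precision(phi, np.zeros(0), ridge=2.0)
        assert np.allclose(P, 2.0 * np.eye(5))
        q = np.random.default_rng(0).standard_normal(5)
        assert q @ np.linalg.solve(P, q) == pytest.approx(q @ q / 2.0)

    def test_adding_a_record_never_increases_variance(self):
        rng = np.random.default_rng(1)
        phi = rng.standard_normal((20, 6)) / np.sqrt(6)
        probs = rng.uniform(0.1, 0.9, size=20)
        queries = rng.standard_normal((10, 6))
        P = laplace_precision(phi[:-1], probs[:-1], 1.0)
        P_full = laplace_precision(phi, probs, 1.0)
        v_before = np.einsum("ij,ji->i", queries, np.linalg.solve(P, queries.T))
        v_after = np.einsum("ij,ji->i", queries, np.linalg.solve(P_full, queries.T))
        assert np.all(v_after <= v_before + 1e-12)

    def test_sequential_rank_one_equals_batch(self):
        rng = np.random.default_rng(2)
        phi = rng.standard_normal((15, 4))
        probs = rng.uniform(0.05, 0.95, size=15)
        P_seq = 0.5 * np.eye(4)
        for row, p in zip(phi, probs):
            P_seq += p * (1 - p) * np.outer(row, row)
        P_batch = laplace_precision(phi, probs, 0.5)
        assert np.allclose(P_seq, P_batch, atol=1e-8)

    def test_eigenvalues_at_least_ridge(self):
        rng = np.random.default_rng(3)
        P = laplace_precision(
            rng.standard_normal((30, 5)), rng.uniform(0.2, 0.8, 30), ridge=0.3
        )
        assert np.all(np.linalg.eigvalsh(P) >= 0.3 - 1e-10)

    def test_nonfinite_probabilities_abort(self):
        with pytest.raises(FloatingPointError):
            laplace_precision(np.zeros((2, 3)), np.array([0.5, np.nan]), 1.0)


class TestLatentToProbability:
    def test_zero_variance_is_plain_sigmoid(self):
        m = np.array([-2.0, 0.0, 3.0])
        assert np.allclose(latent_to_probability(m, np.zeros(3)), sigmoid(m))

    def test_large_variance_shrinks_to_half(self):
        p = latent_to_probability(np.array([5.0, -7.0]), np.array([1e8, 1e8]))
        assert np.allclose(p, 0.5, atol=1e-3)

    def test_adjusted_probability_between_sigmoid_and_half(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(-4, 4, 200)
        v = rng.uniform(0, 10, 200)
        p = latent_to_probability(m, v)
        lo = np.minimum(sigmoid(m), 0.5)
        hi = np.maximum(sigmoid(m), 0.5)
        assert np.all((p >= lo - 1e-12) & (p <= hi + 1e-12))

    def test_plain_mode_ignores_variance(self):
        m = np.array([1.0, -1.0])
        assert np.allclose(
            latent_to_probability(m, np.array([5.0, 5.0]), mode="plain"), sigmoid(m)
        )

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            latent_to_probability(np.zeros(1), np.array([-1.0]))


class TestFittedSNGP:
    def test_variance_lower_in_dense_region(self, toy_arrays):
        # dense edge of the training density vs far outside the square;
        # raw (unnormalized) GP input makes the far point genuinely far
        import pandas as pd

        from logituq.cohort import Cohort

        cfg = TrainConfig(hidden=(16, 16), residual=True, max_epochs=10, patience=3)
        res = SNGPClassifier(
            toy_arrays["X_tr"],
            toy_arrays["y_tr"],
            toy_arrays["X_val"],
            toy_arrays["y_val"],
            config=cfg,
            n_rff=512,
            length_scale=2.0,
            input_norm=False,
            seed=2,
        ).fit()
        enc = toy_arrays["encoder"]
        inside = pd.DataFrame(
            {"x0": [0.5], "x1": [0.9], "label": [0], "true_p1": [0.0]}
        )
        outside = pd.DataFrame(
            {"x0": [6.0], "x1": [6.0], "label": [0], "true_p1": [0.0]}
        )
        schema = {"x0": "continuous", "x1": "continuous", "label": "label", "true_p1": "truth"}
        z_in = enc.transform(Cohort(inside, schema)).X
        z_out = enc.transform(Cohort(outside, schema)).X
        _, v_in = res.predict_latent(z_in)
        _, v_out = res.predict_latent(z_out)
        assert v_out[0] >= 2.0 * v_in[0]

    def test_infinite_ridge_kills_variance(self, toy_arrays):
        cfg = TrainConfig(hidden=(8,), residual=True, max_epochs=3, patience=3)
        res = SNGPClassifier(
            toy_arrays["X_tr"][:200],
            toy_arrays["y_tr"][:200],
            toy_arrays["X_val"][:50],
            toy_arrays["y_val"][:50],
            config=cfg,
            n_rff=64,
            ridge=1e9,
            seed=0,
        ).fit()
        _, var = res.predict_latent(toy_arrays["X_val"][:20])
        assert np.all(var < 1e-6)

    def test_variance_ignores_label_values_given_probabilities(self, small_sngp, toy_arrays):
        # recompute the precision with permuted labels but frozen fitted
        # probabilities: the predictive variance must not change
        from scipy.linalg import cho_factor, cho_solve

        net = small_sngp.net
        phi = net.rff.transform(net.features(small_sngp.model.X_train))
        probs = sigmoid(phi @ net.beta)
        P = laplace_precision(phi, probs, small_sngp.model.ridge)
        assert np.allclose(P, small_sngp.precision)
        X = toy_arrays["X_val"][:10]
        _, var = small_sngp.predict_latent(X)
        phi_q = net.rff.transform(net.features(X))
        var_direct = np.einsum(
            "ij,ji->i", phi_q, cho_solve(cho_factor(P, lower=True), phi_q.T)
        )
        assert np.allclose(var, var_direct)

    def test_spectral_bound_enforced_on_fitted_weights(self, small_sngp):
        net = small_sngp.net
        mats = [net.Win] + [blk["W"] for blk in net.blocks]
        for W in mats:
            top = np.linalg.svd(W, compute_uv=False)[0]
            assert top <= small_sngp.model.sn_bound + 1e-8

    def test_gaussian_posterior_is_sampling_free(self, small_sngp, toy_arrays):
        posterior = small_sngp.predict_logit_posterior(toy_arrays["X_val"][:6])
        assert posterior.is_gaussian
        assert posterior.samples is None

    def test_unequal_hidden_widths_rejected(self, toy_arrays):
        with pytest.raises(ValueError, match="equal hidden widths"):
            SNGPClassifier(
                toy_arrays["X_tr"],
                toy_arrays["y_tr"],
                toy_arrays["X_val"],
                toy_arrays["y_val"],
                config=TrainConfig(hidden=(16, 8), residual=True),
            )

    def test_summary_reports_head(self, small_sngp):
        text = small_sngp.summary()
        assert "RFF features" in text and "256" in text
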