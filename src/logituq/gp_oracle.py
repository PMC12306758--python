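"""Exact Gaussian-process reference and the mean-reversion check.

With a distance-decaying kernel, observations far from a query point carry
no information about the latent function there: the joint prior between
the query value and the distant latents factorizes, so the posterior
predictive at the query reverts to the prior predictive.  The same holds
when local observations are fully noisy (the local likelihood is flat).
This module provides the exact conditional-Gaussian machinery to
demonstrate both limits, a Laplace-form binary-label fit comparable to the
SNGP head, and a reusable check that asserts reversion along a ray leaving
the data support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist

from .backbone import sigmoid

__all__ = [
    "ExactGP",
    "gp_posterior",
    "LaplaceBinaryGP",
    "fit_laplace_binary",
    "LocalityPartition",
    "locality_partition",
    "MeanReversionResult",
    "mean_reversion_check",
]


@dataclass
class ExactGP:
    """Zero-or-constant-mean GP with an RBF kernel.

    ``variance`` is the kernel (prior) variance, ``length_scale`` the RBF
    length scale; ``jitter`` stabilizes Cholesky factorizations.
    """

    mean_const: float = 0.0
    variance: float = 1.0
    length_scale: float = 1.0
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.variance <= 0 or self.length_scale <= 0:
            raise ValueError("kernel variance and length scale must be positive")

    def kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        sq = cdist(A, B, metric="sqeuclidean")
        return self.variance * np.exp(-0.5 * sq / self.length_scale**2)


def gp_posterior(
    gp: ExactGP,
    x_star: np.ndarray,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    noise_var: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at ``x_star`` by conditional Gaussians.

    With no training data the prior ``(m, k(x,x))`` is returned exactly.
    ``noise_var`` is a scalar or per-observation Gaussian noise variance.
    """
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    prior_var = np.full(len(x_star), gp.variance)
    if X is None or len(X) == 0:
        return np.full(len(x_star), gp.mean_const), prior_var
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    noise = np.broadcast_to(np.asarray(noise_var, dtype=float), (len(X),))
    K = gp.kernel(X, X) + np.diag(noise) + gp.jitter * np.eye(len(X))
    chol = cho_factor(K, lower=True)
    ks = gp.kernel(X, x_star)  # (n, m)
    alpha = cho_solve(chol, y - gp.mean_const)
    mean = gp.mean_const + ks.T @ alpha
    v = cho_solve(chol, ks)
    var = prior_var - np.einsum("ij,ij->j", ks, v)
    return mean, np.maximum(var, 0.0)


@dataclass
class LaplaceBinaryGP:
    """Laplace-approximated GP binary classifier (latent-space interface)."""

    gp: ExactGP
    X: np.ndarray
    f_hat: np.ndarray
    grad: np.ndarray  # y - sigmoid(f_hat)
    sqrt_w: np.ndarray
    chol_B: np.ndarray

    def predict_latent(self, x_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ks = self.gp.kernel(self.X, np.atleast_2d(x_star))
        mean = self.gp.mean_const + ks.T @ self.grad
        v = solve_triangular(self.chol_B, self.sqrt_w[:, None] * ks, lower=True)
        var = self.gp.variance - np.einsum("ij,ij->j", v, v)
        return mean, np.maximum(var, 0.0)


def fit_laplace_binary(
    gp: ExactGP,
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LaplaceBinaryGP:
    """Laplace mode finding for Bernoulli-logit labels (Newton iteration).

    The implied Gaussian pseudo-likelihood has per-point weight
    p_i (1 - p_i), matching the Laplace covariance used by the SNGP head.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = gp.kernel(X, X) + gp.jitter * np.eye(n)
    f = np.full(n, gp.mean_const)
    for _ in range(max_iter):
        p = sigmoid(f)
        w = p * (1.0 - p)
        sw = np.sqrt(w)
        B = np.eye(n) + sw[:, None] * K * sw[None, :]
        L = np.linalg.cholesky(B)
        b = w * (f - gp.mean_const) + (y - p)
        inner = solve_triangular(L, sw * (K @ b), lower=True)
        a = b - sw * solve_triangular(L.T, inner, lower=False)
        f_new = gp.mean_const + K @ a
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    p = sigmoid(f)
    w = p * (1.0 - p)
    sw = np.sqrt(w)
    B = np.eye(n) + sw[:, None] * K * sw[None, :]
    return LaplaceBinaryGP(
        gp=gp, X=X, f_hat=f, grad=y - p, sqrt_w=sw, chol_B=np.linalg.cholesky(B)
    )


@dataclass
class LocalityPartition:
    """Training data split into a ball around the query and its complement."""

    local_idx: np.ndarray
    outer_idx: np.ndarray
    max_outer_kernel: float


def locality_partition(
    gp: ExactGP, x_star: np.ndarray, X: np.ndarray, r: float
) -> LocalityPartition:
    """Partition by Euclidean distance: local = within radius ``r``."""
    if r <= 0:
        raise ValueError("radius must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = np.linalg.norm(X - np.asarray(x_star, dtype=float)[None, :], axis=1)
    local = np.flatnonzero(d <= r)
    outer = np.flatnonzero(d > r)
    max_k = (
        float(gp.kernel(X[outer], np.atleast_2d(x_star)).max()) if len(outer) else 0.0
    )
    return LocalityPartition(local_idx=local, outer_idx=outer, max_outer_kernel=max_k)


@dataclass
class MeanReversionResult:
    """Distance profile of the latent posterior along a ray leaving the data."""

    distances: np.ndarray
    mean_dev: np.ndarray  # |latent mean - prior reference|
    variance: np.ndarray
    prior_mean: float
    prior_var: float
    mean_monotone: bool
    mean_far_ok: bool
    var_monotone: bool
    var_far_ok: bool | None

    @property
    def passed(self) -> bool:
        checks = [self.mean_monotone, self.mean_far_ok, self.var_monotone]
        if self.var_far_ok is not None:
            checks.append(self.var_far_ok)
        return all(checks)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance": self.distances,
                "mean_dev": self.mean_dev,
                "variance": self.variance,
            }
        )


def mean_reversion_check(
    predict_latent: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    prior_mean: float,
    prior_var: float,
    ray: np.ndarray,
    *,
    mean_tol: float,
    noise_tol: float = 0.0,
    var_noise_tol: float | None = None,
    var_tol: float | None = None,
    distances: np.ndarray | None = None,
) -> MeanReversionResult:
    """Assert reversion to the prior along ``ray`` (ordered near -> far).

    Checks that |latent mean - prior_mean| decreases weakly (within
    ``noise_tol``) and ends below ``mean_tol``, and that the variance
    increases weakly (within ``var_noise_tol``) toward the prior variance
    (within ``var_tol`` at the far end, when given).
    """
    ray = np.atleast_2d(np.asarray(ray, dtype=float))
    mean, var = predict_latent(ray)
    dev = np.abs(np.asarray(mean, dtype=float) - prior_mean)
    var = np.asarray(var, dtype=float)
    if distances is None:
        distances = np.linalg.norm(ray - ray[0], axis=1)
    vnt = noise_tol if var_noise_tol is None else var_noise_tol
    return MeanReversionResult(
        distances=distances,
        mean_dev=dev,
        variance=var,
        prior_mean=prior_mean,
        prior_var=prior_var,
        mean_monotone=bool(np.all(np.diff(dev) <= noise_tol)),
        mean_far_ok=bool(dev[-1] <= mean_tol),
        var_monotone=bool(np.all(np.diff(var) >= -vnt)),
        var_far_ok=None if var_tol is None else bool(abs(var[-1] - prior_var) <= var_tol),
    )
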