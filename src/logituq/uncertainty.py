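"""Instance-wise uncertainty measures in logit space.

All measures operate on the latent log-odds (logits), never on sigmoid
probabilities, so that uncertainty is decoupled from the prior class
frequency.  Given a per-instance posterior over the log-odds l1|x and the
training prior log-odds l1 = log(n1/n0):

* Bayes factor        K     = exp(l1|x - l1)
* evidential strength ES    = |E[l1|x] - l1|
* total uncertainty   u_tot = exp(-k ES)            in (0, 1]
* epistemic           u_epi = 1 - exp(-k Var[l1|x]) in [0, 1)

``k`` is a decay rate fixing the visualization scale; every ranking built
from u_tot or u_epi is invariant to it, because both transforms are
strictly monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LogitPosterior",
    "UncertaintyScores",
    "prior_log_odds",
    "bayes_factor",
    "evidential_strength",
    "total_uncertainty",
    "epistemic_uncertainty",
    "score_instances",
]


@dataclass
class LogitPosterior:
    """Per-instance posterior over the latent log-odds.

    Either *sample form* (``samples`` of shape ``(n, M)``: M posterior
    draws per instance, e.g. ensemble member logits) or *Gaussian form*
    (``gauss_mean``/``gauss_var`` of shape ``(n,)``, e.g. the closed-form
    SNGP latent posterior).
    """

    samples: np.ndarray | None = None
    gauss_mean: np.ndarray | None = None
    gauss_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.samples is None) == (self.gauss_mean is None):
            raise ValueError("provide exactly one of sample or Gaussian form")
        if self.samples is not None:
            self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
            if self.samples.shape[1] < 1:
                raise ValueError("sample form needs M >= 1 draws")
        else:
            self.gauss_mean = np.asarray(self.gauss_mean, dtype=float)
            self.gauss_var = np.asarray(self.gauss_var, dtype=float)
            if self.gauss_var is None or self.gauss_var.shape != self.gauss_mean.shape:
                raise ValueError("Gaussian form needs matching mean and variance")
            if np.any(self.gauss_var < 0):
                raise ValueError("Gaussian variance must be non-negative")

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "LogitPosterior":
        return cls(samples=samples)

    @classmethod
    def from_gaussian(cls, mean: np.ndarray, var: np.ndarray) -> "LogitPosterior":
        return cls(gauss_mean=mean, gauss_var=var)

    @property
    def is_gaussian(self) -> bool:
        return self.samples is None

    @property
    def n_instances(self) -> int:
        if self.samples is not None:
            return self.samples.shape[0]
        return len(self.gauss_mean)

    @property
    def n_draws(self) -> int | None:
        return None if self.samples is None else self.samples.shape[1]

    def mean(self) -> np.ndarray:
        if self.samples is not None:
            return self.samples.mean(axis=1)
        return self.gauss_mean

    def variance(self) -> np.ndarray:
        """Unbiased sample variance of the draws, or the stored variance."""
        if self.samples is None:
            return self.gauss_var
        if self.samples.shape[1] < 2:
            warnings.warn(
                "sample variance undefined for M = 1; returning 0", RuntimeWarning
            )
            return np.zeros(self.samples.shape[0])
        return self.samples.var(axis=1, ddof=1)


def prior_log_odds(labels: np.ndarray) -> float:
    """log(count(1) / count(0)) over the training labels."""
    labels = np.asarray(labels, dtype=int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to estimate prior log-odds")
    return float(np.log(n1 / n0))


def bayes_factor(posterior_log_odds: np.ndarray, l1: float) -> np.ndarray:
    """K = exp(l1|x - l1); K = 1 is neutral evidence."""
    return np.exp(np.asarray(posterior_log_odds, dtype=float) - l1)


def evidential_strength(posterior: LogitPosterior, l1: float) -> np.ndarray:
    """ES = |E[l1|x] - l1|: absolute log Bayes factor of the mean prediction."""
    return np.abs(posterior.mean() - l1)


def total_uncertainty(es: np.ndarray, k: float = 1.0) -> np.ndarray:
    """u_tot = exp(-k ES): 1 at neutral evidence, -> 0 for overwhelming evidence."""
    if k <= 0:
        raise ValueError("decay rate k must be positive")
    es = np.asarray(es, dtype=float)
    if np.any(es < 0):
        raise ValueError("evidential strength must be non-negative")
    return np.exp(-k * es)


def epistemic_uncertainty(posterior: LogitPosterior, k: float = 1.0) -> np.ndarray:
    """u_epi = 1 - exp(-k Var[l1|x]): 0 for a delta posterior, -> 1 as Var -> inf."""
    if k <= 0:
        raise ValueError("decay rate k must be positive")
    return 1.0 - np.exp(-k * posterior.variance())


@dataclass
class UncertaintyScores:
    """Per-instance evidential strength and transformed uncertainty measures."""

    es: np.ndarray
    u_tot: np.ndarray
    u_epi: np.ndarray
    l1: float
    k: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"es": self.es, "u_tot": self.u_tot, "u_epi": self.u_epi}
        ).assign(l1=self.l1, k=self.k)


def score_instances(
    posterior: LogitPosterior, l1: float, k: float = 1.0
) -> UncertaintyScores:
    """Vectorized ES / u_tot / u_epi over a cohort.

    The Gaussian-form path uses the stored moments directly and never
    samples.
    """
    es = evidential_strength(posterior, l1)
    return UncertaintyScores(
        es=es,
        u_tot=total_uncertainty(es, k),
        u_epi=epistemic_uncertainty(posterior, k),
        l1=l1,
        k=k,
    )
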