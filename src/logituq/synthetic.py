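"""Synthetic data with known ground truth.

Two generators feed the pipeline:

* a 2D *toy* distribution whose class probability ramps linearly along one
  axis (``x0``) while the training-data density ramps linearly along the
  orthogonal axis (``x1``) — the two mechanisms are statistically
  independent, so epistemic uncertainty (data sparsity, a function of
  ``x1``) and aleatoric uncertainty (label noise ``p1(1-p1)``, a function
  of ``x0``) are fully disentangled in the ground truth;
* a screening-registry-style *cohort* with mixed categorical/continuous features,
  missing-completely-at-random entries, a linear ground-truth logit and a
  low target prevalence, standing in for a restricted-access clinical
  registry.

Both laws carry their own seed; identical law -> bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort

__all__ = [
    "ToyLaw",
    "CohortLaw",
    "sample_toy_train",
    "sample_toy_test",
    "true_density",
    "true_label_noise",
    "sample_cohort",
    "default_cohort_law",
]


# ---------------------------------------------------------------------------
# 2D toy law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyLaw:
    """Generative law of the 2D toy dataset.

    ``p1(x0) = clip(alpha + beta * x0, 0, 1)`` is the class-1 probability;
    ``w(x1) = density_intercept + density_slope * x1`` is the training
    density along ``x1`` and must be positive and integrate to one over
    ``x1_range``.  With the defaults the dense edge of the square carries
    seven times the density of the sparse edge.
    """

    x0_range: tuple[float, float] = (0.0, 1.0)
    x1_range: tuple[float, float] = (0.0, 1.0)
    alpha: float = 0.0
    beta: float = 1.0
    density_intercept: float = 0.25
    density_slope: float = 1.5
    n_train: int = 4000
    n_test: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        lo0, hi0 = self.x0_range
        lo1, hi1 = self.x1_range
        if not (hi0 > lo0 and hi1 > lo1):
            raise ValueError("domain ranges must be non-degenerate")
        a, b = self.density_intercept, self.density_slope
        if a + b * lo1 <= 0 or a + b * hi1 <= 0:
            raise ValueError("training density w(x1) must be positive on the domain")
        integral = a * (hi1 - lo1) + 0.5 * b * (hi1**2 - lo1**2)
        if abs(integral - 1.0) > 1e-9:
            raise ValueError(
                f"w(x1) must integrate to 1 over x1_range (got {integral:.6g})"
            )
        if self.n_train < 0 or self.n_test < 0:
            raise ValueError("sample sizes must be non-negative")

    # -- ground-truth functions --------------------------------------------

    def p1(self, x0: np.ndarray) -> np.ndarray:
        return np.clip(self.alpha + self.beta * np.asarray(x0, dtype=float), 0.0, 1.0)

    def density_weight(self, x1: np.ndarray) -> np.ndarray:
        return self.density_intercept + self.density_slope * np.asarray(x1, dtype=float)

    def _check_domain(self, x0: np.ndarray, x1: np.ndarray) -> None:
        lo0, hi0 = self.x0_range
        lo1, hi1 = self.x1_range
        if np.any((x0 < lo0) | (x0 > hi0)) or np.any((x1 < lo1) | (x1 > hi1)):
            raise ValueError("points outside the law's domain")


def _sample_linear_density(law: ToyLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from w(x1) = a + b*x1 on x1_range."""
    lo, hi = law.x1_range
    a, b = law.density_intercept, law.density_slope
    u = rng.uniform(size=n)
    if b == 0.0:
        return lo + u * (hi - lo)
    # CDF(x) = a (x - lo) + b/2 (x^2 - lo^2); solve the quadratic for x
    c = u + a * lo + 0.5 * b * lo**2
    return (-a + np.sqrt(a**2 + 2.0 * b * c)) / b


def _toy_cohort(x0: np.ndarray, x1: np.ndarray, y: np.ndarray, p1: np.ndarray) -> Cohort:
    frame = pd.DataFrame({"x0": x0, "x1": x1, "label": y.astype(int), "true_p1": p1})
    schema = {"x0": "continuous", "x1": "continuous", "label": "label", "true_p1": "truth"}
    return Cohort(frame, schema)


def sample_toy_train(law: ToyLaw) -> Cohort:
    """Training draw: x0 uniform, x1 from the linear density, Bernoulli labels."""
    rng = np.random.default_rng(np.random.SeedSequence([law.seed, 0]))
    lo0, hi0 = law.x0_range
    x0 = rng.uniform(lo0, hi0, size=law.n_train)
    x1 = _sample_linear_density(law, law.n_train, rng)
    p1 = law.p1(x0)
    y = rng.uniform(size=law.n_train) < p1
    return _toy_cohort(x0, x1, y, p1)


def sample_toy_test(law: ToyLaw) -> Cohort:
    """Test draw: both coordinates uniform on the domain, same label law."""
    rng = np.random.default_rng(np.random.SeedSequence([law.seed, 1]))
    lo0, hi0 = law.x0_range
    lo1, hi1 = law.x1_range
    x0 = rng.uniform(lo0, hi0, size=law.n_test)
    x1 = rng.uniform(lo1, hi1, size=law.n_test)
    p1 = law.p1(x0)
    y = rng.uniform(size=law.n_test) < p1
    return _toy_cohort(x0, x1, y, p1)


def true_density(law: ToyLaw, points: np.ndarray) -> np.ndarray:
    """Training density p(x0, x1), normalized over the domain."""
    pts = np.asarray(points, dtype=float)
    x0, x1 = pts[:, 0], pts[:, 1]
    law._check_domain(x0, x1)
    lo0, hi0 = law.x0_range
    return law.density_weight(x1) / (hi0 - lo0)


def true_label_noise(law: ToyLaw, points: np.ndarray) -> np.ndarray:
    """Aleatoric label noise p1 (1 - p1); a pure function of x0."""
    pts = np.asarray(points, dtype=float)
    x0, x1 = pts[:, 0], pts[:, 1]
    law._check_domain(x0, x1)
    p = law.p1(x0)
    return p * (1.0 - p)


# ---------------------------------------------------------------------------
# Screening-registry-style synthetic cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortLaw:
    """Generative law of the synthetic clinical cohort.

    Categorical features are declared as ``{name: per-level effect array}``
    (the number of levels is the array length); continuous features as
    ``{name: coefficient}`` on standard-normal draws.  The intercept is
    calibrated at sampling time so that the expected prevalence matches
    ``prevalence``.  Missingness is applied after label generation and is
    independent of everything (MCAR).
    """

    categorical_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    continuous_effects: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    prevalence: float = 0.07
    n: int = 7664
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, eff in self.categorical_effects.items():
            if len(eff) < 2:
                raise ValueError(f"categorical feature {name!r} needs >= 2 levels")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {name!r} must be in [0, 1)")
            if name not in self.categorical_effects and name not in self.continuous_effects:
                raise ValueError(f"missing rate given for unknown feature {name!r}")


def default_cohort_law(n: int = 7664, seed: int = 0, prevalence: float = 0.07) -> CohortLaw:
    """Screening-registry-style default: staging/grade/treatment-style categoricals,
    lab-and-lifestyle-style continuous features, realistic missingness."""
    return CohortLaw(
        categorical_effects={
            "stage": (0.0, 0.7, 1.5, 2.6),
            "grade": (0.0, 0.6, 1.2),
            "histology": (0.0, 0.3, 0.9),
            "primary_treatment": (0.0, -0.4, 0.3, 0.1),
            "race": (0.0, 0.1, -0.1, 0.05, 0.0),
            "smoker": (0.0, 0.25),
        },
        continuous_effects={
            "psa_log": 0.9,
            "age": 0.5,
            "bmi": 0.1,
            "cig_years": 0.2,
            "comorbidity_index": 0.3,
        },
        missing_rates={
            "psa_log": 0.05,
            "bmi": 0.10,
            "cig_years": 0.20,
            "comorbidity_index": 0.15,
            "histology": 0.05,
            "smoker": 0.02,
        },
        prevalence=prevalence,
        n=n,
        seed=seed,
    )


def _level_probs(n_levels: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed, mildly non-uniform level frequencies (seeded by the law)."""
    raw = rng.gamma(shape=4.0, scale=1.0, size=n_levels)
    return raw / raw.sum()


def sample_cohort(law: CohortLaw) -> Cohort:
    """Draw a cohort; ground-truth logits/probabilities stored as truth columns."""
    rng = np.random.default_rng(np.random.SeedSequence([law.seed, 2]))
    n = law.n
    eta = np.zeros(n)
    columns: dict[str, np.ndarray] = {}
    schema: dict[str, str] = {}

    for name, effects in law.categorical_effects.items():
        probs = _level_probs(len(effects), rng)
        codes = rng.choice(len(effects), size=n, p=probs)
        eta += np.asarray(effects)[codes]
        columns[name] = np.array([f"L{c}" for c in codes], dtype=object)
        schema[name] = "categorical"

    for name, coef in law.continuous_effects.items():
        z = rng.standard_normal(n)
        eta += coef * z
        columns[name] = z
        schema[name] = "continuous"

    # calibrate the intercept so that E[sigmoid(c + eta)] hits the target
    def gap(c: float) -> float:
        return float(np.mean(expit(c + eta))) - law.prevalence

    lo, hi = -40.0, 40.0
    if n == 0:
        intercept = float(logit(law.prevalence))
    else:
        if gap(lo) > 0 or gap(hi) < 0:
            raise ValueError(
                "prevalence target unreachable given the ground-truth logit range: "
                f"target={law.prevalence}, attainable="
                f"[{np.mean(expit(lo + eta)):.3g}, {np.mean(expit(hi + eta)):.3g}]"
            )
        intercept = brentq(gap, lo, hi, xtol=1e-12)

    true_logit = intercept + eta
    true_p = expit(true_logit)
    y = rng.uniform(size=n) < true_p

    # MCAR missingness, applied after label generation
    for name, rate in law.missing_rates.items():
        if rate == 0.0:
            continue
        mask = rng.uniform(size=n) < rate
        if schema[name] == "categorical":
            col = columns[name].copy()
            col[mask] = np.nan
            columns[name] = col
        else:
            col = columns[name].astype(float).copy()
            col[mask] = np.nan
            columns[name] = col

    frame = pd.DataFrame(columns)
    frame["label"] = y.astype(int)
    frame["true_logit"] = true_logit
    frame["true_p"] = true_p
    schema["label"] = "label"
    schema["true_logit"] = "truth"
    schema["true_p"] = "truth"
    return Cohort(frame, schema)
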