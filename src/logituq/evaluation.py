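"""Population-level metrics and uncertainty-ranked stratification.

Discrimination (AUROC/AUPRC) delegates to scikit-learn, rank correlation
to scipy; calibration (ECE, reliability curves), the per-instance negative
log-likelihood, and the sliding-window stratification of NLL by an
uncertainty ranking are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from .synthetic import ToyLaw, true_density, true_label_noise

__all__ = [
    "auroc",
    "auprc",
    "ece",
    "calibration_curve",
    "nll",
    "instance_nll",
    "StratificationResult",
    "sliding_window_stratification",
    "spearman",
    "correlate_uncertainty_with",
    "curvature_profile",
]

NLL_FLOOR = 1e-12  # probability clip keeping log-likelihoods finite


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def auroc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (the Mann-Whitney concordance probability)."""
    return float(roc_auc_score(_check_binary(labels), probabilities))


def auprc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision)."""
    return float(average_precision_score(_check_binary(labels), probabilities))


def calibration_curve(
    probabilities: np.ndarray, labels: np.ndarray, bins: int = 10
) -> pd.DataFrame:
    """Per-bin (mean probability, empirical frequency, count); equal-width
    bins over [0, 1], empty bins omitted."""
    if bins < 1:
        raise ValueError("need at least one bin")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_probability": float(p[mask].mean()),
                "empirical_frequency": float(y[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def ece(probabilities: np.ndarray, labels: np.ndarray, bins: int = 10) -> float:
    """Expected calibration error: bin-weighted |confidence - accuracy|."""
    curve = calibration_curve(probabilities, labels, bins)
    n = int(curve["count"].sum())
    gaps = np.abs(curve["mean_probability"] - curve["empirical_frequency"])
    return float(np.sum(curve["count"] / n * gaps))


def instance_nll(probabilities: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-instance negative Bernoulli log-likelihood, probability-clipped."""
    p = np.clip(np.asarray(probabilities, dtype=float), NLL_FLOOR, 1.0 - NLL_FLOOR)
    y = np.asarray(labels, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def nll(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative Bernoulli log-likelihood."""
    return float(np.mean(instance_nll(probabilities, labels)))


@dataclass
class StratificationResult:
    """NLL over sliding windows of instances ranked by uncertainty.

    ``window_mean_nll[i]`` is the mean NLL of window i (stride 1 over
    instances sorted ascending by uncertainty, stable ties); windows are
    ``n - w + 1`` in number.  ``spearman`` correlates window rank with
    window mean NLL; ``constant_uncertainty`` flags an undefined ranking.
    """

    window_mean_nll: np.ndarray
    window_sum_nll: np.ndarray
    window: int
    stride: int
    spearman: float | None
    nll_span_mean: float | None
    nll_span_sum: float | None
    constant_uncertainty: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.window_mean_nll)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_rank": np.arange(self.n_windows),
                "mean_nll": self.window_mean_nll,
                "sum_nll": self.window_sum_nll,
            }
        )


def sliding_window_stratification(
    per_instance_nll: np.ndarray,
    uncertainty: np.ndarray,
    window: int | None = None,
    stride: int = 1,
) -> StratificationResult:
    """Rank instances by uncertainty and profile NLL over sliding windows.

    Default window size is one-third of the data; windows advance by one
    instance.  Ties in uncertainty are broken by stable original order.
    """
    values = np.asarray(per_instance_nll, dtype=float)
    unc = np.asarray(uncertainty, dtype=float)
    if len(values) != len(unc):
        raise ValueError("nll and uncertainty must have equal length")
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 instances")
    w = n // 3 if window is None else int(window)
    if not (1 <= w <= n):
        raise ValueError("window size out of range")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    order = np.argsort(unc, kind="stable")
    sorted_nll = values[order]
    csum = np.concatenate([[0.0], np.cumsum(sorted_nll)])
    starts = np.arange(0, n - w + 1, stride)
    sums = csum[starts + w] - csum[starts]
    means = sums / w
    if np.all(unc == unc[0]):
        return StratificationResult(
            window_mean_nll=means,
            window_sum_nll=sums,
            window=w,
            stride=stride,
            spearman=None,
            nll_span_mean=None,
            nll_span_sum=None,
            constant_uncertainty=True,
        )
    rho = spearman(np.arange(len(means), dtype=float), means)
    return StratificationResult(
        window_mean_nll=means,
        window_sum_nll=sums,
        window=w,
        stride=stride,
        spearman=rho,
        nll_span_mean=float(means[-1] - means[0]),
        nll_span_sum=float(sums[-1] - sums[0]),
    )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rho, _ = spearmanr(x, y)
    return float(rho)


def correlate_uncertainty_with(
    law: ToyLaw,
    points: np.ndarray,
    u_epi: np.ndarray,
    target: str = "density",
) -> tuple[float, pd.DataFrame]:
    """Spearman of epistemic uncertainty against a toy ground-truth field.

    ``target`` is ``"density"`` (training density p(x0, x1)) or
    ``"label_noise"`` (aleatoric noise p1 (1 - p1)).  Returns the
    coefficient and the paired values for export.
    """
    if target == "density":
        field_values = true_density(law, points)
    elif target == "label_noise":
        field_values = true_label_noise(law, points)
    else:
        raise ValueError(f"unknown target {target!r}")
    rho = spearman(np.asarray(u_epi, dtype=float), field_values)
    pairs = pd.DataFrame({"u_epi": u_epi, target: field_values})
    return rho, pairs


def curvature_profile(p: np.ndarray) -> np.ndarray:
    """Loss-curvature scaling of the logit variance: 1 / (p (1 - p)).

    Under a second-order (Laplace-style) view of cross-entropy training,
    the logit variance inflates exactly where the sigmoid saturates —
    symmetric about 1/2 with minimum 4 — which is how implicit-prior
    models end up entangling epistemic estimates with aleatoric noise.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    return 1.0 / (p * (1.0 - p))
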