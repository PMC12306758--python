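"""Deep ensembles: a particle-based approximate posterior.

M independently initialized, independently trained networks whose logits
at a query point form M draws from an implicit functional posterior.
Diversity stems from initialization and shuffling seeds only (no bagging).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .backbone import PointMLP, TrainConfig, TrainingTrace, sigmoid, train_supervised
from .uncertainty import LogitPosterior, UncertaintyScores, score_instances

__all__ = ["DeepEnsembleClassifier", "DeepEnsembleResults"]


class DeepEnsembleClassifier:
    """Ensemble of point-estimate MLPs for binary classification.

    Parameters
    ----------
    X_train, y_train, X_val, y_val
        Encoded design matrices and binary labels; validation data drives
        early stopping of every member.
    n_members
        Ensemble size M.  M = 1 degenerates to a single network with zero
        epistemic spread.
    config
        Shared architecture and optimization settings; each member gets a
        distinct seed derived from ``seed``.
    """

    def __init__(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        *,
        n_members: int = 50,
        config: TrainConfig | None = None,
        seed: int = 0,
    ):
        if n_members < 1:
            raise ValueError("n_members must be >= 1")
        self.X_train = np.asarray(X_train, dtype=float)
        self.y_train = np.asarray(y_train, dtype=float)
        self.X_val = np.asarray(X_val, dtype=float)
        self.y_val = np.asarray(y_val, dtype=float)
        self.n_members = n_members
        self.config = config or TrainConfig()
        self.seed = seed

    def fit(self) -> "DeepEnsembleResults":
        members: list[PointMLP] = []
        traces: list[TrainingTrace] = []
        seeds = np.random.SeedSequence([self.seed, 3]).generate_state(self.n_members)
        d_in = self.X_train.shape[1]
        for m, member_seed in enumerate(seeds):
            try:
                member = PointMLP(d_in, self.config.hidden, int(member_seed))
                cfg = replace(self.config, seed=int(member_seed))
                trace = train_supervised(
                    member,
                    (self.X_train, self.y_train),
                    (self.X_val, self.y_val),
                    cfg,
                )
            except Exception as exc:  # noqa: BLE001 - annotate member index
                raise RuntimeError(f"training of ensemble member {m} failed") from exc
            members.append(member)
            traces.append(trace)
        return DeepEnsembleResults(model=self, members=members, traces=traces)


@dataclass
class DeepEnsembleResults:
    model: DeepEnsembleClassifier
    members: list[PointMLP]
    traces: list[TrainingTrace]

    def predict_logit_samples(self, X: np.ndarray) -> LogitPosterior:
        """Sample-form posterior: draw i is member i's latent log-odds."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.model.X_train.shape[1]:
            raise ValueError(
                f"expected {self.model.X_train.shape[1]} features, got {X.shape[1]}"
            )
        samples = np.column_stack([m.predict_logits(X) for m in self.members])
        return LogitPosterior.from_samples(samples)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior predictive class-1 probability: mean member sigmoid."""
        posterior = self.predict_logit_samples(X)
        return sigmoid(posterior.samples).mean(axis=1)

    def uncertainty(self, X: np.ndarray, l1: float, k: float = 1.0) -> UncertaintyScores:
        return score_instances(self.predict_logit_samples(X), l1, k)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Deep ensemble classifier",
            f"  members:          {len(self.members)}",
            f"  architecture:     {self.model.X_train.shape[1]} -> "
            + " -> ".join(map(str, cfg.hidden))
            + " -> 1",
            f"  training records: {len(self.model.y_train)}",
            f"  median best epoch: {int(np.median([t.best_epoch for t in self.traces]))}",
            f"  median val loss:   {float(np.median([t.best_val_loss for t in self.traces])):.4f}",
        ]
        return "\n".join(lines)
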