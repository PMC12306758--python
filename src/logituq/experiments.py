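"""Config-driven experiment runners.

Two end-to-end experiments mirror the study design:

* ``run_cohort_experiment`` — six-fold 4:1:1 cross-validation of all three
  model families on the synthetic clinical cohort, reporting AUROC, AUPRC,
  ECE and NLL per fold plus sliding-window stratification of NLL by the
  total- and epistemic-uncertainty rankings (pooled over test folds);
* ``run_toy_experiment`` — train on the density-ramped 2D toy
  distribution, evaluate on its uniform-density counterpart, and export
  epistemic uncertainty against predicted probability, true data density
  and true label noise, plus a mean-reversion profile for SNGP.

All randomness flows from a single seed; reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import TrainConfig, sigmoid
from .bnn import RadialBNNClassifier
from .cohort import Cohort
from .ensemble import DeepEnsembleClassifier
from .evaluation import (
    auprc,
    auroc,
    ece,
    instance_nll,
    nll,
    sliding_window_stratification,
    spearman,
)
from .gp_oracle import mean_reversion_check
from .preprocessing import CohortEncoder, make_splits
from .sngp import SNGPClassifier
from .synthetic import (
    CohortLaw,
    ToyLaw,
    default_cohort_law,
    sample_cohort,
    sample_toy_test,
    sample_toy_train,
    true_density,
    true_label_noise,
)
from .uncertainty import prior_log_odds, score_instances

logger = logging.getLogger(__name__)

MODEL_NAMES = ("enn", "bnn", "sngp")

__all__ = [
    "ExperimentConfig",
    "desk_config",
    "full_config",
    "run_cohort_experiment",
    "run_toy_experiment",
    "run_reproduce",
]


@dataclass
class ExperimentConfig:
    """Shared configuration of both experiments.

    The ``full`` preset keeps the study-scale settings (ensemble of 500,
    4096 random Fourier features); the ``desk`` preset trades ensemble and
    feature counts for minutes-scale runtime without changing the data
    laws.
    """

    models: tuple[str, ...] = MODEL_NAMES
    n_members: int = 50
    bnn_draws: int = 200
    n_rff: int = 1024
    k: float = 1.0
    ece_bins: int = 10
    n_folds: int = 6
    # shared training settings
    hidden: tuple[int, ...] = (32, 32)
    learning_rate: float = 5e-3
    batch_size: int = 128
    max_epochs: int = 40
    patience: int = 5
    # SNGP head (operating point chosen on the toy law in place of the
    # source study's architecture grid search)
    length_scale: float = 2.5
    ridge: float = 1.0
    sn_bound: float = 0.5
    # BNN posterior
    prior_scale: float = 1.0
    mc_draws: int = 1
    sigma0: float = 0.1
    # data laws
    cohort_n: int = 7664
    prevalence: float = 0.07
    toy_n_train: int = 4000
    toy_n_test: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models in roster: {sorted(unknown)}")

    def train_config(self, *, residual: bool = False) -> TrainConfig:
        return TrainConfig(
            hidden=tuple(self.hidden),
            residual=residual,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
        )

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("models", "hidden"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def desk_config(seed: int = 0) -> ExperimentConfig:
    """Minutes-scale defaults (ensemble M = 50, D = 1024 features)."""
    return ExperimentConfig(seed=seed)


def full_config(seed: int = 0) -> ExperimentConfig:
    """Study-scale settings: 500 ensemble members, 4096 Fourier features."""
    return ExperimentConfig(
        n_members=500,
        bnn_draws=200,
        n_rff=4096,
        hidden=(128, 128, 128),
        cohort_n=7664,
        seed=seed,
    )


def _fit_model(
    name: str,
    config: ExperimentConfig,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int,
):
    if name == "enn":
        return DeepEnsembleClassifier(
            X_tr,
            y_tr,
            X_val,
            y_val,
            n_members=config.n_members,
            config=config.train_config(),
            seed=seed,
        ).fit()
    if name == "bnn":
        return RadialBNNClassifier(
            X_tr,
            y_tr,
            X_val,
            y_val,
            config=config.train_config(),
            prior_scale=config.prior_scale,
            mc_draws=config.mc_draws,
            sigma0=config.sigma0,
            seed=seed,
        ).fit()
    if name == "sngp":
        width = config.hidden[0]
        sngp_train = TrainConfig(
            hidden=(width,) * len(config.hidden),
            residual=True,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.patience,
        )
        return SNGPClassifier(
            X_tr,
            y_tr,
            X_val,
            y_val,
            config=sngp_train,
            n_rff=config.n_rff,
            length_scale=config.length_scale,
            ridge=config.ridge,
            sn_bound=config.sn_bound,
            seed=seed,
        ).fit()
    raise ValueError(f"unknown model {name!r}")


def _predict(name: str, results, X: np.ndarray, config: ExperimentConfig, seed: int):
    """(posterior, probability) on a query matrix."""
    if name == "bnn":
        posterior = results.predict_logit_samples(X, config.bnn_draws, seed=seed)
        prob = sigmoid(posterior.samples).mean(axis=1)
    elif name == "enn":
        posterior = results.predict_logit_samples(X)
        prob = sigmoid(posterior.samples).mean(axis=1)
    else:
        posterior = results.predict_logit_posterior(X)
        prob = results.predict_proba(X)
    return posterior, prob


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _write_manifest(outdir: Path, config: ExperimentConfig, seed: int, files: list[str]) -> None:
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "outputs": sorted(files),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


@dataclass
class CohortExperimentResult:
    metrics: pd.DataFrame
    aggregate: pd.DataFrame
    stratification: dict[str, dict[str, object]]
    scores: dict[str, pd.DataFrame]
    failures: list[str] = field(default_factory=list)


def run_cohort_experiment(
    config: ExperimentConfig,
    outdir: str | Path,
    seed: int | None = None,
    cohort: Cohort | None = None,
) -> CohortExperimentResult:
    """Six-fold cross-validation of the model roster on the synthetic cohort."""
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        law = default_cohort_law(
            n=config.cohort_n, seed=_derived_seed(seed, 10), prevalence=config.prevalence
        )
        cohort = sample_cohort(law)
    plan = make_splits(cohort.labels, seed=_derived_seed(seed, 11), n_folds=config.n_folds)

    metric_rows = []
    pooled: dict[str, list[pd.DataFrame]] = {m: [] for m in config.models}
    failures: list[str] = []
    for fold_idx, fold in enumerate(plan.folds):
        try:
            encoder = CohortEncoder().fit(cohort, fold["train"])
            enc_tr = encoder.transform(cohort, fold["train"])
            enc_val = encoder.transform(cohort, fold["val"])
            enc_te = encoder.transform(cohort, fold["test"])
            l1 = prior_log_odds(enc_tr.y)
        except Exception as exc:  # noqa: BLE001
            logger.error("fold %d preprocessing failed: %s", fold_idx, exc)
            failures.append(f"fold {fold_idx}: {exc}")
            continue
        for m_idx, name in enumerate(config.models):
            try:
                model_seed = _derived_seed(seed, 12, fold_idx, m_idx)
                results = _fit_model(
                    name, config, enc_tr.X, enc_tr.y, enc_val.X, enc_val.y, model_seed
                )
                posterior, prob = _predict(name, results, enc_te.X, config, model_seed)
                scores = score_instances(posterior, l1, config.k)
                metric_rows.append(
                    {
                        "model": name,
                        "fold": fold_idx,
                        "auroc": auroc(prob, enc_te.y),
                        "auprc": auprc(prob, enc_te.y),
                        "ece": ece(prob, enc_te.y, config.ece_bins),
                        "nll": nll(prob, enc_te.y),
                    }
                )
                frame = scores.to_frame()
                frame.insert(0, "instance", fold["test"])
                frame.insert(1, "fold", fold_idx)
                frame["probability"] = prob
                frame["label"] = enc_te.y
                frame["nll"] = instance_nll(prob, enc_te.y)
                pooled[name].append(frame)
            except Exception as exc:  # noqa: BLE001
                logger.error("fold %d model %s failed: %s", fold_idx, name, exc)
                failures.append(f"fold {fold_idx}/{name}: {exc}")

    metrics = pd.DataFrame(metric_rows)
    aggregate = (
        metrics.groupby("model")[["auroc", "auprc", "ece", "nll"]]
        .agg(["mean", "std"])
        .reset_index()
        if len(metrics)
        else pd.DataFrame()
    )
    files = []
    metrics.to_csv(outdir / "metrics.csv", index=False)
    files.append("metrics.csv")
    if len(aggregate):
        aggregate.to_csv(outdir / "aggregate.csv", index=False)
        files.append("aggregate.csv")

    stratification: dict[str, dict[str, object]] = {}
    scores_out: dict[str, pd.DataFrame] = {}
    for name in config.models:
        if not pooled[name]:
            continue
        frame = pd.concat(pooled[name], ignore_index=True)
        scores_out[name] = frame
        frame.to_csv(outdir / f"scores_{name}.csv", index=False)
        files.append(f"scores_{name}.csv")
        stratification[name] = {}
        for measure in ("u_tot", "u_epi"):
            # both u_tot and u_epi increase with uncertainty
            strat = sliding_window_stratification(
                frame["nll"].to_numpy(), frame[measure].to_numpy()
            )
            stratification[name][measure] = strat
            strat.to_frame().to_csv(
                outdir / f"stratification_{name}_{measure}.csv", index=False
            )
            files.append(f"stratification_{name}_{measure}.csv")
    _write_manifest(outdir, config, seed, files)
    return CohortExperimentResult(
        metrics=metrics,
        aggregate=aggregate,
        stratification=stratification,
        scores=scores_out,
        failures=failures,
    )


@dataclass
class ToyExperimentResult:
    law: ToyLaw
    tables: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    reversion: object | None
    failures: list[str] = field(default_factory=list)


def _stratified_holdout(labels: np.ndarray, frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified split into (train, validation) index arrays."""
    rng = np.random.default_rng(seed)
    val_parts, train_parts = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_val = max(1, int(round(frac * len(idx))))
        val_parts.append(idx[:n_val])
        train_parts.append(idx[n_val:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(val_parts))


def run_toy_experiment(
    config: ExperimentConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> ToyExperimentResult:
    """Train on the density-ramped toy law; evaluate on its uniform twin."""
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    law = ToyLaw(
        n_train=config.toy_n_train, n_test=config.toy_n_test, seed=_derived_seed(seed, 20)
    )
    train = sample_toy_train(law)
    test = sample_toy_test(law)
    tr_idx, val_idx = _stratified_holdout(train.labels, 1.0 / 6.0, _derived_seed(seed, 21))
    encoder = CohortEncoder().fit(train, tr_idx)
    enc_tr = encoder.transform(train, tr_idx)
    enc_val = encoder.transform(train, val_idx)
    enc_te = encoder.transform(test)
    l1 = prior_log_odds(enc_tr.y)

    points = test.frame[["x0", "x1"]].to_numpy()
    density = true_density(law, points)
    noise = true_label_noise(law, points)

    tables: dict[str, pd.DataFrame] = {}
    corr_rows = []
    reversion = None
    failures: list[str] = []
    files: list[str] = []
    for m_idx, name in enumerate(config.models):
        try:
            model_seed = _derived_seed(seed, 22, m_idx)
            results = _fit_model(
                name, config, enc_tr.X, enc_tr.y, enc_val.X, enc_val.y, model_seed
            )
            posterior, prob = _predict(name, results, enc_te.X, config, model_seed)
            scores = score_instances(posterior, l1, config.k)
            table = pd.DataFrame(
                {
                    "x0": points[:, 0],
                    "x1": points[:, 1],
                    "label": test.labels,
                    "true_p1": test.truth("true_p1"),
                    "density": density,
                    "label_noise": noise,
                    "probability": prob,
                    "es": scores.es,
                    "u_tot": scores.u_tot,
                    "u_epi": scores.u_epi,
                    "nll": instance_nll(prob, test.labels),
                }
            )
            tables[name] = table
            table.to_csv(outdir / f"toy_{name}.csv", index=False)
            files.append(f"toy_{name}.csv")
            for target, values in (("density", density), ("label_noise", noise)):
                corr_rows.append(
                    {
                        "model": name,
                        "target": target,
                        "spearman": spearman(scores.u_epi, values),
                    }
                )
            if name == "sngp":
                # ray leaving the data support: from the domain corner outward
                t = np.linspace(0.0, 8.0, 40)
                direction = np.array([1.0, 1.0]) / np.sqrt(2.0)
                ray = np.array([1.0, 1.0])[None, :] + t[:, None] * direction[None, :]
                ray_cohort_X = encoder.transform(
                    Cohort(
                        pd.DataFrame(
                            {"x0": ray[:, 0], "x1": ray[:, 1], "label": 0, "true_p1": 0.0}
                        ),
                        dict(train.schema),
                    )
                ).X
                reversion = mean_reversion_check(
                    lambda Z: results.predict_latent(Z),
                    prior_mean=0.0,
                    prior_var=1.0 / config.ridge,
                    ray=ray_cohort_X,
                    mean_tol=np.inf,  # recorded; assertions live with the caller
                    distances=t,
                )
                reversion.to_frame().to_csv(outdir / "sngp_mean_reversion.csv", index=False)
                files.append("sngp_mean_reversion.csv")
        except Exception as exc:  # noqa: BLE001
            logger.error("toy model %s failed: %s", name, exc)
            failures.append(f"{name}: {exc}")
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(outdir / "correlations.csv", index=False)
    files.append("correlations.csv")
    _write_manifest(outdir, config, seed, files)
    return ToyExperimentResult(
        law=law,
        tables=tables,
        correlations=correlations,
        reversion=reversion,
        failures=failures,
    )


def run_reproduce(
    config: ExperimentConfig, outdir: str | Path, seed: int | None = None
) -> tuple[CohortExperimentResult, ToyExperimentResult]:
    """Both experiments end to end under one seed."""
    outdir = Path(outdir)
    cohort_res = run_cohort_experiment(config, outdir / "cohort", seed)
    toy_res = run_toy_experiment(config, outdir / "toy", seed)
    return cohort_res, toy_res
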