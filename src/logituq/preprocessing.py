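"""Feature encoding and the stratified six-fold 4:1:1 split plan.

Categorical features become one indicator column per level observed in the
fitting subset plus a dedicated "missing" indicator; continuous features
are standardized with statistics from the fitting subset only, missing
values are imputed with 0 (the post-standardization mean) and flagged with
an auxiliary binary column.  Fitting on the training subset of a fold and
transforming everything else prevents information leakage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = ["ColumnInfo", "EncodedMatrix", "CohortEncoder", "SplitPlan", "make_splits"]


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one encoded column."""

    source: str  # original feature name
    role: str  # "level" | "missing" | "value" | "missing_flag"
    level: str | None = None  # level label for role == "level"


@dataclass
class EncodedMatrix:
    """Dense design matrix with provenance map and label vector."""

    X: np.ndarray
    columns: list[ColumnInfo]
    y: np.ndarray

    def source_features(self) -> set[str]:
        return {c.source for c in self.columns}


class CohortEncoder:
    """One-hot + missing-flag encoder with train-subset standardization."""

    def __init__(self) -> None:
        self.levels_: dict[str, list[str]] = {}
        self.center_: dict[str, float] = {}
        self.scale_: dict[str, float] = {}
        self.columns_: list[ColumnInfo] | None = None

    def fit(self, cohort: Cohort, rows: np.ndarray | None = None) -> "CohortEncoder":
        frame = cohort.frame if rows is None else cohort.frame.iloc[rows]
        self.levels_.clear()
        self.center_.clear()
        self.scale_.clear()
        columns: list[ColumnInfo] = []
        for col in cohort.categorical_columns:
            observed = sorted(
                {str(v) for v in frame[col].dropna().unique()},
            )
            self.levels_[col] = observed
            columns.extend(ColumnInfo(col, "level", lv) for lv in observed)
            columns.append(ColumnInfo(col, "missing"))
        for col in cohort.continuous_columns:
            values = frame[col].astype(float)
            center = float(values.mean(skipna=True))
            scale = float(values.std(skipna=True, ddof=0))
            if not np.isfinite(center):
                center = 0.0
            if not np.isfinite(scale) or scale == 0.0:
                scale = 1.0
            self.center_[col] = center
            self.scale_[col] = scale
            columns.append(ColumnInfo(col, "value"))
            columns.append(ColumnInfo(col, "missing_flag"))
        self.columns_ = columns
        return self

    def transform(self, cohort: Cohort, rows: np.ndarray | None = None) -> EncodedMatrix:
        if self.columns_ is None:
            raise RuntimeError("encoder not fitted")
        frame = cohort.frame if rows is None else cohort.frame.iloc[rows]
        n = len(frame)
        blocks: list[np.ndarray] = []
        for col in cohort.categorical_columns:
            levels = self.levels_[col]
            raw = frame[col]
            is_missing = raw.isna().to_numpy()
            as_str = raw.astype("string").fillna("")
            block = np.zeros((n, len(levels) + 1))
            for j, lv in enumerate(levels):
                block[:, j] = (as_str == lv).to_numpy(dtype=float)
            unseen = ~is_missing & (block[:, :-1].sum(axis=1) == 0)
            if unseen.any():
                logger.warning(
                    "%d unseen level(s) in %r mapped to the missing indicator",
                    int(unseen.sum()),
                    col,
                )
            block[:, -1] = (is_missing | unseen).astype(float)
            blocks.append(block)
        for col in cohort.continuous_columns:
            values = frame[col].to_numpy(dtype=float)
            missing = ~np.isfinite(values)
            std = (values - self.center_[col]) / self.scale_[col]
            std[missing] = 0.0
            blocks.append(np.column_stack([std, missing.astype(float)]))
        X = np.hstack(blocks) if blocks else np.empty((n, 0))
        y = frame[cohort.label_col].to_numpy(dtype=int)
        return EncodedMatrix(X=X, columns=list(self.columns_), y=y)

    def fit_transform(self, cohort: Cohort, rows: np.ndarray | None = None) -> EncodedMatrix:
        return self.fit(cohort, rows).transform(cohort, rows)


@dataclass
class SplitPlan:
    """Index sets for six-fold 4:1:1 train/validation/test cross-validation.

    Test sets are pairwise disjoint and cover every record; each fold's
    validation set is the next test block in cyclic order, so each fold
    uses four blocks for training.
    """

    folds: list[dict[str, np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        n = sum(len(f["test"]) for f in self.folds)
        all_test = np.concatenate([f["test"] for f in self.folds])
        if len(np.unique(all_test)) != n:
            raise ValueError("test folds must be pairwise disjoint")
        for f in self.folds:
            roles = np.concatenate([f["train"], f["val"], f["test"]])
            if len(np.unique(roles)) != len(roles) or len(roles) != n:
                raise ValueError("each fold must partition all records")

    def __len__(self) -> int:
        return len(self.folds)

    def save(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "folds": [
                {role: idx.tolist() for role, idx in fold.items()} for fold in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        folds = [
            {role: np.asarray(idx, dtype=int) for role, idx in fold.items()}
            for fold in payload["folds"]
        ]
        return cls(folds=folds, seed=payload["seed"])


def make_splits(labels: np.ndarray, seed: int, n_folds: int = 6) -> SplitPlan:
    """Stratified permutation split into ``n_folds`` blocks; fold k uses
    block k as test, block k+1 (cyclic) as validation, the rest as train."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    if n < 2 * n_folds or counts.min() < n_folds:
        raise ValueError(
            f"cannot stratify {n_folds} folds: need >= {n_folds} members per class"
        )
    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = [np.empty(0, dtype=int)] * n_folds
    for cls_value in classes:
        idx = np.flatnonzero(labels == cls_value)
        idx = rng.permutation(idx)
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            blocks[k] = np.concatenate([blocks[k], chunk])
    folds = []
    for k in range(n_folds):
        test = np.sort(blocks[k])
        val = np.sort(blocks[(k + 1) % n_folds])
        train = np.sort(
            np.concatenate([blocks[j] for j in range(n_folds) if j not in (k, (k + 1) % n_folds)])
        )
        folds.append({"train": train, "val": val, "test": test})
    return SplitPlan(folds=folds, seed=seed)
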