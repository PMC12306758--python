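"""Tabular cohort container: feature table, labels, and a column schema.

A :class:`Cohort` is the common currency of the pipeline: a pandas frame
plus a schema declaring each column as categorical feature, continuous
feature, the binary label, or generator ground truth (``truth`` columns are
never exposed to models).  Serialization is CSV with a YAML sidecar schema;
missing entries are written as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = {"categorical", "continuous", "label", "truth"}


@dataclass
class Cohort:
    frame: pd.DataFrame
    schema: dict[str, str]

    def __post_init__(self) -> None:
        for col, kind in self.schema.items():
            if kind not in VALID_KINDS:
                raise ValueError(f"unknown column kind {kind!r} for {col!r}")
            if col not in self.frame.columns:
                raise ValueError(f"schema column {col!r} missing from frame")
        undeclared = set(self.frame.columns) - set(self.schema)
        if undeclared:
            raise ValueError(f"columns without schema entry: {sorted(undeclared)}")
        labels = [c for c, k in self.schema.items() if k == "label"]
        if len(labels) != 1:
            raise ValueError("schema must declare exactly one label column")
        self.label_col = labels[0]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k in ("categorical", "continuous")]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k == "categorical"]

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k == "continuous"]

    @property
    def truth_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k == "truth"]

    @property
    def labels(self) -> np.ndarray:
        return self.frame[self.label_col].to_numpy(dtype=int)

    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    def truth(self, col: str) -> np.ndarray:
        if self.schema.get(col) != "truth":
            raise KeyError(f"{col!r} is not a truth column")
        return self.frame[col].to_numpy(dtype=float)

    def subset(self, rows: np.ndarray) -> "Cohort":
        return Cohort(self.frame.iloc[rows].reset_index(drop=True), dict(self.schema))

    # -- serialization ------------------------------------------------------

    def save(self, base: str | Path) -> tuple[Path, Path]:
        """Write ``<base>.csv`` and ``<base>.schema.yaml``."""
        base = Path(base)
        base.parent.mkdir(parents=True, exist_ok=True)
        csv_path = base.with_suffix(".csv")
        schema_path = base.with_suffix(".schema.yaml")
        self.frame.to_csv(csv_path, index=False, na_rep="")
        schema_path.write_text(yaml.safe_dump(self.schema, sort_keys=False))
        return csv_path, schema_path

    @classmethod
    def load(cls, base: str | Path) -> "Cohort":
        base = Path(base)
        schema = yaml.safe_load(base.with_suffix(".schema.yaml").read_text())
        dtypes: dict[str, object] = {
            c: float for c, k in schema.items() if k in ("continuous", "truth")
        }
        dtypes.update({c: object for c, k in schema.items() if k == "categorical"})
        frame = pd.read_csv(base.with_suffix(".csv"), dtype=dtypes)
        return cls(frame, schema)
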