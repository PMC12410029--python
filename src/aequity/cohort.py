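"""Tabular cohort container.

A cohort is a pandas DataFrame with a fixed column convention:

- ``subject_id`` — string identifier; all rows of one subject share a group
- ``group`` — categorical sensitive attribute
- ``y_<name>`` — one column per candidate binary outcome (0/1)
- remaining numeric columns — features (by convention ``f0, f1, ...``)

Precomputed embeddings are supported through a dense ``.npy`` matrix plus
an aligned metadata table carrying subject_id, group and the outcome
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Cohort", "CohortError", "load_cohort", "load_embeddings"]

OUTCOME_PREFIX = "y_"


class CohortError(ValueError):
    """Cohort structure violates the container contract."""


@dataclass
class Cohort:
    data: pd.DataFrame
    feature_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise CohortError(f"cohort is missing required column '{col}'")
        if not self.feature_cols:
            reserved = {"subject_id", "group"}
            self.feature_cols = [
                c
                for c in df.columns
                if c not in reserved and not c.startswith(OUTCOME_PREFIX)
            ]
        if not self.feature_cols:
            raise CohortError("cohort has no feature columns")
        if not self.outcome_names:
            raise CohortError(f"cohort has no outcome columns ('{OUTCOME_PREFIX}<name>')")
        for name in self.outcome_names:
            col = df[OUTCOME_PREFIX + name]
            if col.isna().any():
                raise CohortError(f"outcome '{name}' has missing values")
            if not set(np.unique(col)).issubset({0, 1}):
                raise CohortError(f"outcome '{name}' must be binary 0/1")
        grp_per_subject = df.groupby("subject_id")["group"].nunique()
        if (grp_per_subject > 1).any():
            bad = grp_per_subject[grp_per_subject > 1].index[0]
            raise CohortError(f"subject '{bad}' appears in more than one group")

    # -- views -------------------------------------------------------------
    @property
    def outcome_names(self) -> list[str]:
        return [c[len(OUTCOME_PREFIX):] for c in self.data.columns if c.startswith(OUTCOME_PREFIX)]

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].astype(str).unique())

    @property
    def n(self) -> int:
        return len(self.data)

    def counts_by_group(self) -> dict[str, int]:
        vc = self.data["group"].astype(str).value_counts()
        return {g: int(vc.get(g, 0)) for g in self.groups}

    def features(self) -> np.ndarray:
        return self.data[self.feature_cols].to_numpy(dtype=np.float64)

    def outcome(self, name: str) -> np.ndarray:
        col = OUTCOME_PREFIX + name
        if col not in self.data.columns:
            raise CohortError(f"unknown outcome '{name}' (have {self.outcome_names})")
        return self.data[col].to_numpy(dtype=np.int64)

    def group_labels(self) -> np.ndarray:
        return self.data["group"].astype(str).to_numpy()

    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].astype(str).to_numpy()

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.data.loc[np.asarray(mask)].reset_index(drop=True), list(self.feature_cols))

    def restrict_group(self, group: str) -> "Cohort":
        return self.subset(self.group_labels() == group)

    def restrict_stratum(self, outcome: str, value: int) -> "Cohort":
        return self.subset(self.outcome(outcome) == value)

    # -- io ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def to_parquet(self, path: str | Path) -> None:
        self.data.to_parquet(path, index=False)


def load_cohort(path: str | Path) -> Cohort:
    """Read a cohort from CSV or Parquet by extension."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return Cohort(df)


def load_embeddings(npy_path: str | Path, meta_path: str | Path) -> Cohort:
    """Assemble a cohort from a dense embedding matrix and aligned metadata.

    The metadata table must carry subject_id, group and the ``y_*`` outcome
    columns; row i of the matrix is the embedding of metadata row i.
    """
    emb = np.load(npy_path)
    meta_df = (
        pd.read_parquet(meta_path) if str(meta_path).endswith(".parquet") else pd.read_csv(meta_path)
    )
    if emb.ndim != 2 or emb.shape[0] != len(meta_df):
        raise CohortError(
            f"embedding matrix has {emb.shape[0] if emb.ndim == 2 else '?'} rows, "
            f"metadata has {len(meta_df)}"
        )
    feat_cols = [f"e{j}" for j in range(emb.shape[1])]
    df = pd.concat(
        [meta_df.reset_index(drop=True), pd.DataFrame(emb, columns=feat_cols)], axis=1
    )
    return Cohort(df, feat_cols)
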