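"""Labeled dataset assembly and SMOTE class balancing.

SMOTE (synthetic minority oversampling) equalizes the three saddle-height
classes to the majority class count by interpolating new rows between a
minority sample and one of its k nearest same-class neighbours:
``x_new = x_i + u * (x_nn - x_i)`` with ``u ~ Uniform(0, 1)``. Original
rows are preserved verbatim and synthetic rows are flagged in a
``provenance`` vector; synthetic rows inherit the subject id of their base
sample so subject-wise splitting stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from saddlefit.features import FEATURE_NAMES, FeatureTable

__all__ = ["LabeledDataset", "smote_balance"]

REAL, SYNTHETIC = "real", "synthetic_smote"


@dataclass
class LabeledDataset:
    """Feature matrix with labels, subject ids and per-row provenance
    (``real`` or ``synthetic_smote``)."""

    X: pd.DataFrame
    y: np.ndarray
    subjects: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        self.provenance = np.asarray(self.provenance)
        if not (len(self.y) == len(self.subjects) == len(self.provenance) == n):
            raise ValueError("X, y, subjects and provenance must share length")

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_feature_table(cls, table: FeatureTable) -> "LabeledDataset":
        return cls(X=table.X.reset_index(drop=True), y=table.y.copy(),
                   subjects=table.subjects.copy(),
                   provenance=np.full(len(table), REAL, dtype=object))

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_csv(self, path: str | Path) -> None:
        df = self.X.copy()
        df["label"] = self.y
        df["subject_id"] = self.subjects
        df["provenance"] = self.provenance
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        df = pd.read_csv(path)
        cols = [c for c in FEATURE_NAMES if c in df.columns] or [
            c for c in df.columns
            if c not in ("label", "subject_id", "provenance")]
        return cls(X=df[cols], y=df["label"].to_numpy(),
                   subjects=df["subject_id"].to_numpy(),
                   provenance=df.get(
                       "provenance",
                       pd.Series([REAL] * len(df))).to_numpy())


def smote_balance(data: LabeledDataset, k_neighbors: int = 5,
                  seed: int = 0) -> LabeledDataset:
    """Oversample minority classes to the majority class count.

    Every class must have at least ``k_neighbors + 1`` rows (neighbours are
    searched among the class's own samples, excluding the sample itself).
    Deterministic for a fixed seed. Features should already be on
    commensurate scales (e.g. normalized): the neighbour search is
    Euclidean.
    """
    counts = data.class_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to balance")
    for label, c in counts.items():
        if c < k_neighbors + 1:
            raise ValueError(
                f"class {label} has only {c} rows; SMOTE with k={k_neighbors} "
                f"needs at least {k_neighbors + 1} (use a smaller k)")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    X = data.X.to_numpy(dtype=float)

    new_X, new_y, new_subj = [], [], []
    for label in sorted(counts):
        deficit = target - counts[label]
        if deficit == 0:
            continue
        idx = np.flatnonzero(data.y == label)
        Xc = X[idx]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)
        neigh = neigh[:, 1:]  # drop self
        base = rng.integers(0, len(idx), size=deficit)
        pick = rng.integers(0, k_neighbors, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        x_i = Xc[base]
        x_nn = Xc[neigh[base, pick]]
        new_X.append(x_i + u[:, None] * (x_nn - x_i))
        new_y.append(np.full(deficit, label, dtype=data.y.dtype))
        new_subj.append(data.subjects[idx[base]])

    if not new_X:
        return LabeledDataset(data.X.copy(), data.y.copy(),
                              data.subjects.copy(), data.provenance.copy())
    synth = pd.DataFrame(np.concatenate(new_X), columns=data.X.columns)
    return LabeledDataset(
        X=pd.concat([data.X.reset_index(drop=True), synth],
                    ignore_index=True),
        y=np.concatenate([data.y, *new_y]),
        subjects=np.concatenate([data.subjects, *new_subj]),
        provenance=np.concatenate([
            data.provenance,
            np.full(sum(len(a) for a in new_y), SYNTHETIC, dtype=object)]),
    )
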