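"""Random-forest ligandability classifier for inner pocket points.

The classifier is trained on the raw, imbalanced point dataset — no
over/under-sampling and no class weights, since rebalancing degrades
generalization for this task.  The 0.5 decision threshold is used only for
reporting precision/recall/MCC; pocket scoring consumes the raw
positive-class probability P1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "PointDataset",
    "TrainedModel",
    "ConfusionCounts",
    "SchemaMismatchError",
    "precision",
    "recall",
    "mcc",
    "confusion_metrics",
    "train",
    "predict_p1",
    "cross_validate",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


class SchemaMismatchError(ValueError):
    """Feature schema of the input does not match the model's schema."""


@dataclass
class PointDataset:
    """Labeled inner-point feature matrix with per-protein group keys."""

    X: np.ndarray                 # (n, n_features)
    y: np.ndarray                 # (n,) in {0, 1}
    groups: np.ndarray            # (n,) protein ids
    feature_names: list[str]
    schema_version: str
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2 or len(self.X) != len(self.y) != len(self.groups):
            raise ValueError("X, y, groups must align")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def subset(self, mask: np.ndarray) -> "PointDataset":
        meta = self.meta.loc[mask].reset_index(drop=True) if self.meta is not None else None
        return PointDataset(self.X[mask], self.y[mask], self.groups[mask],
                            self.feature_names, self.schema_version, meta)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "protein_id", self.groups)
        df.insert(1, "label", self.y)
        return df

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.attrs["schema_version"] = self.schema_version
        with open(path, "w") as fh:
            fh.write(f"# schema_version={self.schema_version}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointDataset":
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("# schema_version="):
                raise ValueError(f"{path}: missing schema_version header")
            schema = first.split("=", 1)[1]
            df = pd.read_csv(fh)
        features = [c for c in df.columns if c not in ("protein_id", "label")]
        return cls(df[features].to_numpy(), df["label"].to_numpy(),
                   df["protein_id"].to_numpy(), features, schema)


@dataclass
class TrainedModel:
    """A fitted forest plus the feature schema it was trained against."""

    forest: RandomForestClassifier
    schema_version: str
    feature_names: list[str]
    metadata: dict

    def check_schema(self, schema_version: str) -> None:
        if schema_version != self.schema_version:
            raise SchemaMismatchError(
                f"model schema {self.schema_version!r} != input schema "
                f"{schema_version!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0.0 when no positive predictions exist."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0.0 when no actual positives exist."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when the denominator vanishes."""
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / sqrt(denom)


def confusion_metrics(c: ConfusionCounts) -> dict:
    """All three statistics plus a flag marking zero-denominator cases."""
    degenerate = (c.tp + c.fp == 0 or c.tp + c.fn == 0
                  or c.tn + c.fp == 0 or c.tn + c.fn == 0)
    return {"precision": precision(c), "recall": recall(c), "mcc": mcc(c),
            "degenerate": degenerate}


def train(dataset: PointDataset, n_trees: int = 100, seed: int = 0) -> TrainedModel:
    """Fit a random forest on the raw imbalanced dataset.

    Deterministic for a fixed seed.  Raises on single-class input.
    """
    neg, pos = dataset.class_counts
    if neg == 0 or pos == 0:
        raise ValueError(f"dataset must contain both classes (neg={neg}, pos={pos})")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(dataset.X, dataset.y)
    return TrainedModel(
        forest=forest,
        schema_version=dataset.schema_version,
        feature_names=list(dataset.feature_names),
        metadata={"seed": int(seed), "n_trees": int(n_trees),
                  "class_counts": {"negative": neg, "positive": pos}},
    )


def predict_p1(model: TrainedModel, X: np.ndarray,
               schema_version: str | None = None) -> np.ndarray:
    """Positive-class probability P1 for each feature row.

    The forest's class histogram per point is the pair [P0, P1] with
    P0 + P1 = 1; P1 drives the pocket score.
    """
    if schema_version is not None:
        model.check_schema(schema_version)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise SchemaMismatchError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}")
    proba = model.forest.predict_proba(X)
    pos_col = int(np.flatnonzero(model.forest.classes_ == 1)[0])
    return proba[:, pos_col]


def cross_validate(dataset: PointDataset, k: int = 5, repeats: int = 1,
                   seed: int = 0, n_trees: int = 100) -> dict:
    """Repeated k-fold cross-validation grouped by protein.

    Folds are built over whole proteins (group keys) so points of one
    protein never straddle the train/test boundary.  Returns per-fold rows
    and the mean precision/recall/MCC.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    unique_groups = np.unique(dataset.groups)
    if len(unique_groups) < k:
        raise ValueError(f"need at least {k} protein groups, have {len(unique_groups)}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(unique_groups)
        folds = np.array_split(perm, k)
        for fold_idx, test_groups in enumerate(folds):
            test_mask = np.isin(dataset.groups, test_groups)
            model = train(dataset.subset(~test_mask), n_trees=n_trees,
                          seed=int(rng.integers(2**31)))
            p1 = predict_p1(model, dataset.X[test_mask])
            c = ConfusionCounts.from_labels(dataset.y[test_mask],
                                            (p1 >= 0.5).astype(int))
            rows.append({"repeat": rep, "fold": fold_idx,
                         "test_groups": tuple(sorted(test_groups)),
                         **confusion_metrics(c)})
    folds_df = pd.DataFrame(rows)
    return {
        "folds": folds_df,
        "precision": float(folds_df["precision"].mean()),
        "recall": float(folds_df["recall"].mean()),
        "mcc": float(folds_df["mcc"].mean()),
    }


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({
        "format_version": _MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "schema_version": model.schema_version,
        "feature_names": model.feature_names,
        "metadata": model.metadata,
    }, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - joblib raises various types
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"{path} is not a recognized model file")
    return TrainedModel(
        forest=payload["forest"],
        schema_version=payload["schema_version"],
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )
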