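"""Learned observation likelihoods: a decision tree mapping windowed sensor
vectors to distributions over the eight action classes, used to weight
latent states during filtering.

Two training protocols exist: *optimistic* trains and tests on the same
corpus; *pessimistic* trains on the designated first run only and tests on
the rest (training runs disjoint from test runs).
"""
from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from causact.dynamics import CCBMState
from causact.errors import CausactError, SchemaError

ACTION_CLASSES = ("clean", "drink", "eat", "get", "move", "prepare", "put", "unknown")

__all__ = [
    "ACTION_CLASSES",
    "ClassDistribution",
    "ObservationModelSpec",
    "ObservationModel",
    "train_observation_model",
    "class_distribution",
    "state_weight",
    "uniform_distribution",
]


@dataclass(frozen=True)
class ClassDistribution:
    """Probability per action class at one time step."""

    probs: tuple[float, ...]
    classes: tuple[str, ...] = ACTION_CLASSES

    def __post_init__(self):
        p = np.asarray(self.probs)
        if len(p) != len(self.classes):
            raise CausactError("distribution length does not match the class set")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise CausactError("class distribution must be non-negative and sum to 1")

    def __getitem__(self, cls: str) -> float:
        try:
            return self.probs[self.classes.index(cls)]
        except ValueError:
            raise KeyError(cls)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.classes, self.probs))

    def argmax(self) -> str:
        """Mode class; ties broken by class order (alphabetical by default)."""
        best = int(np.argmax(self.probs))  # np.argmax returns the first max
        order = sorted(range(len(self.classes)), key=lambda i: self.classes[i])
        probs = np.asarray(self.probs)
        for i in order:
            if probs[i] == probs[best]:
                return self.classes[i]
        return self.classes[best]  # pragma: no cover


def uniform_distribution(classes: Sequence[str] = ACTION_CLASSES) -> ClassDistribution:
    n = len(classes)
    return ClassDistribution(tuple([1.0 / n] * n), tuple(classes))


@dataclass
class ObservationModelSpec:
    """Training configuration.

    ``protocol`` is "optimistic" (train = test corpus) or "pessimistic"
    (train on the first run only). Tree hyperparameters default to Gini
    splits with no depth limit and add-one leaf smoothing.
    """

    protocol: str = "optimistic"
    criterion: str = "gini"
    max_depth: int | None = None
    leaf_smoothing: float = 1.0
    features: tuple[str, ...] | None = None
    classes: tuple[str, ...] = ACTION_CLASSES

    def __post_init__(self):
        if self.protocol not in ("optimistic", "pessimistic"):
            raise CausactError(f"unknown protocol {self.protocol!r}")


class ObservationModel:
    """A fitted tree stored as flat node arrays (feature index, threshold,
    children, per-class leaf counts), independent of the fitting backend so
    it round-trips through plain text."""

    def __init__(
        self,
        feature_names: tuple[str, ...],
        classes: tuple[str, ...],
        children_left: np.ndarray,
        children_right: np.ndarray,
        feature: np.ndarray,
        threshold: np.ndarray,
        counts: np.ndarray,  # (n_nodes, n_classes) training counts
        smoothing: float,
        warnings: tuple[str, ...] = (),
    ):
        self.feature_names = tuple(feature_names)
        self.classes = tuple(classes)
        self.children_left = np.asarray(children_left, dtype=int)
        self.children_right = np.asarray(children_right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.counts = np.asarray(counts, dtype=float)
        self.smoothing = float(smoothing)
        self.warnings = tuple(warnings)

    # -- evaluation --------------------------------------------------------

    def _leaf(self, x: np.ndarray) -> int:
        node = 0
        while self.children_left[node] != -1:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return node

    def _vector(self, features: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(features, Mapping):
            missing = [f for f in self.feature_names if f not in features]
            if missing:
                raise SchemaError(f"missing feature(s): {missing}")
            return np.array([float(features[f]) for f in self.feature_names])
        x = np.asarray(features, dtype=float)
        if x.shape != (len(self.feature_names),):
            raise SchemaError(
                f"expected {len(self.feature_names)} feature values, got shape {x.shape}"
            )
        return x

    def predict_distribution(self, features) -> ClassDistribution:
        leaf = self._leaf(self._vector(features))
        counts = self.counts[leaf]
        a = self.smoothing
        probs = (counts + a) / (counts.sum() + a * len(self.classes))
        return ClassDistribution(tuple(probs), self.classes)

    def predict_sequence(self, table: pd.DataFrame) -> list[ClassDistribution]:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        return [
            self.predict_distribution(row)
            for row in table[list(self.feature_names)].to_numpy(dtype=float)
        ]

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "classes": list(self.classes),
                "children_left": self.children_left.tolist(),
                "children_right": self.children_right.tolist(),
                "feature": self.feature.tolist(),
                "threshold": self.threshold.tolist(),
                "counts": self.counts.tolist(),
                "smoothing": self.smoothing,
                "warnings": list(self.warnings),
            },
            indent=1,
        )

    @classmethod
    def from_text(cls, text: str) -> "ObservationModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            classes=tuple(d["classes"]),
            children_left=np.array(d["children_left"]),
            children_right=np.array(d["children_right"]),
            feature=np.array(d["feature"]),
            threshold=np.array(d["threshold"]),
            counts=np.array(d["counts"]),
            smoothing=d["smoothing"],
            warnings=tuple(d["warnings"]),
        )

    def training_report(self, table: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
        """Per-class precision/recall of the argmax prediction on a table."""
        preds = [d.argmax() for d in self.predict_sequence(table)]
        truth = list(table[label_col])
        rows = []
        for c in self.classes:
            tp = sum(1 for p, t in zip(preds, truth) if p == c and t == c)
            fp = sum(1 for p, t in zip(preds, truth) if p == c and t != c)
            fn = sum(1 for p, t in zip(preds, truth) if p != c and t == c)
            rows.append(
                {
                    "class": c,
                    "precision": tp / (tp + fp) if tp + fp else float("nan"),
                    "recall": tp / (tp + fn) if tp + fn else float("nan"),
                    "support": tp + fn,
                }
            )
        return pd.DataFrame(rows)


def train_observation_model(
    windows: pd.DataFrame | Sequence[pd.DataFrame],
    spec: ObservationModelSpec,
    label_col: str = "label",
) -> ObservationModel:
    """Fit the tree on labelled windowed tables.

    Under the pessimistic protocol only the first table is used for
    training. Classes absent from the training data are recorded as
    warnings; smoothing keeps their probability floor positive. Training is
    deterministic given the spec and data order (fixed random state, sorted
    feature order).
    """
    if isinstance(windows, pd.DataFrame):
        tables = [windows]
    else:
        tables = list(windows)
    if not tables:
        raise CausactError("no training tables given")
    train = tables[0] if spec.protocol == "pessimistic" else pd.concat(tables, ignore_index=True)

    feature_names = spec.features
    if feature_names is None:
        feature_names = tuple(sorted(c for c in train.columns if c != label_col))
    else:
        feature_names = tuple(feature_names)
        missing = [f for f in feature_names if f not in train.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")

    labels = list(train[label_col])
    bad = sorted(set(labels) - set(spec.classes))
    if bad:
        raise CausactError(f"labels outside the class set: {bad}")

    warn_msgs = []
    for c in spec.classes:
        if c not in labels:
            msg = f"class {c!r} absent from training data; smoothed floor only"
            warn_msgs.append(msg)
            _warnings.warn(msg)

    X = train[list(feature_names)].to_numpy(dtype=float)
    y = np.array(labels)
    tree = DecisionTreeClassifier(
        criterion=spec.criterion, max_depth=spec.max_depth, random_state=0
    )
    tree.fit(X, y)

    t = tree.tree_
    seen_classes = list(tree.classes_)
    counts = np.zeros((t.node_count, len(spec.classes)))
    # sklearn >= 1.3 normalises tree_.value to frequencies; recover counts
    # via weighted_n_node_samples.
    raw = t.value[:, 0, :]
    scale = t.weighted_n_node_samples
    for j, c in enumerate(seen_classes):
        k = spec.classes.index(c)
        counts[:, k] = raw[:, j] * scale if raw.max() <= 1.0 + 1e-9 else raw[:, j]
    return ObservationModel(
        feature_names=feature_names,
        classes=spec.classes,
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        counts=counts,
        smoothing=spec.leaf_smoothing,
        warnings=tuple(warn_msgs),
    )


def class_distribution(model: ObservationModel, features) -> ClassDistribution:
    """Distribution over action classes for one sensor vector (pure)."""
    return model.predict_distribution(features)


def state_weight(
    dist: ClassDistribution,
    state: CCBMState,
    env_likelihood=None,
) -> float:
    """Likelihood weight of a latent state under one observation.

    The action factor is the distribution's mass on the state's action
    class; the environment factor defaults to 1 (uninformative) and may be
    supplied as a callable of the world state.
    """
    w = dist[state.action.action_class]
    if env_likelihood is not None:
        w *= float(env_likelihood(state.world))
    return float(w)
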