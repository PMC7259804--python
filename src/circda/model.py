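"""Pair descriptors, negative sampling, classifier training and ranking.

A candidate pair (circRNA c, disease d) is described by concatenating the
disease's row of the fused disease similarity S^D (length m) with the
circRNA's row of the fused circRNA similarity S^C (length n): an (m+n)-vector
whose entries say how similar d and c are to every other disease and circRNA.
Known associations are the positive class; an equal number of unknown cells,
sampled uniformly, are the negatives. A binary classifier (SVM by default)
scores candidates; higher score means more likely association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

import pandas as pd

from .containers import AssociationMatrix, SimilarityMatrix

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "TrainingSet",
    "build_pair_descriptor",
    "pair_descriptor_matrix",
    "sample_negatives",
    "build_training_set",
    "train_classifier",
    "score_pairs",
    "rank_unknown_pairs",
]

Pair = tuple[int, int]


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier settings; all fields are recorded on the trained model.

    kind: "svm" (RBF SVC, C=1, gamma by the 1/(n_features*var) scale
    heuristic), or "knn" / "rf" / "dt" for the comparison harness.
    standardize: optional per-feature standardization (off by default —
    similarity rows already share a comparable scale).
    """

    kind: str = "svm"
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: dict | str | None = None
    n_neighbors: int = 5
    n_estimators: int = 100
    standardize: bool = False
    seed: int = 0


def _make_estimator(config: ClassifierConfig):
    if config.kind == "svm":
        est = SVC(kernel="rbf", C=config.C, gamma=config.gamma,
                  class_weight=config.class_weight, random_state=config.seed)
    elif config.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=config.n_neighbors)
    elif config.kind == "rf":
        est = RandomForestClassifier(n_estimators=config.n_estimators,
                                     random_state=config.seed)
    elif config.kind == "dt":
        est = DecisionTreeClassifier(random_state=config.seed)
    else:
        raise ValueError(f"unknown classifier kind {config.kind!r}")
    if config.standardize:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class TrainedModel:
    """Fitted binary scorer plus the configuration that produced it."""

    estimator: object
    config: ClassifierConfig
    n: int  # number of circRNAs (feature block 2 length)
    m: int  # number of diseases (feature block 1 length)

    @property
    def n_features(self) -> int:
        return self.n + self.m

    @property
    def score_kind(self) -> str:
        """'decision' when the scorer exposes a margin, else 'proba'."""
        est = self.estimator
        if isinstance(est, Pipeline):
            est = est.named_steps["clf"]
        return "decision" if hasattr(est, "decision_function") else "proba"

    @property
    def threshold(self) -> float:
        """Positive-call threshold: 0 on margins, 0.5 on probabilities."""
        return 0.0 if self.score_kind == "decision" else 0.5

    def scores(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"descriptor length {X.shape[1]} does not match the model's "
                f"m+n = {self.n_features}"
            )
        if self.score_kind == "decision":
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        return np.asarray(self.estimator.predict_proba(X)[:, 1], dtype=float)


def build_pair_descriptor(
    i_c: int, i_d: int, s_c: SimilarityMatrix, s_d: SimilarityMatrix
) -> np.ndarray:
    """Feature vector F = (S^D row i_d, S^C row i_c), length m + n.

    The disease block comes first; both rows include the pair's own entries
    (self-similarity is part of the profile, not excluded).
    """
    if not 0 <= i_c < s_c.k:
        raise IndexError(f"circRNA index {i_c} out of range for n={s_c.k}")
    if not 0 <= i_d < s_d.k:
        raise IndexError(f"disease index {i_d} out of range for m={s_d.k}")
    return np.concatenate([s_d.values[i_d], s_c.values[i_c]])


def pair_descriptor_matrix(
    pairs: Sequence[Pair], s_c: SimilarityMatrix, s_d: SimilarityMatrix
) -> np.ndarray:
    """Stack descriptors for many pairs (vectorized row gather)."""
    if len(pairs) == 0:
        return np.empty((0, s_d.k + s_c.k))
    idx = np.asarray(pairs, dtype=int)
    if (idx[:, 0] < 0).any() or (idx[:, 0] >= s_c.k).any():
        raise IndexError("circRNA index out of range")
    if (idx[:, 1] < 0).any() or (idx[:, 1] >= s_d.k).any():
        raise IndexError("disease index out of range")
    return np.hstack([s_d.values[idx[:, 1]], s_c.values[idx[:, 0]]])


def sample_negatives(
    acd: AssociationMatrix, count: int | None = None, seed: int = 0
) -> list[Pair]:
    """Uniform sample without replacement from the unknown (0) cells.

    ``count=None`` matches the number of known associations — the balanced
    design used throughout. Deterministic for a given seed; never intersects
    the positives by construction.
    """
    zeros = np.argwhere(acd.values == 0)
    if count is None:
        count = acd.n_positive
    if count > len(zeros):
        raise ValueError(
            f"requested {count} negatives but only {len(zeros)} unknown cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(zeros), size=count, replace=False)
    return [tuple(zeros[i]) for i in chosen]


@dataclass
class TrainingSet:
    """Labeled pairs with their stacked descriptors."""

    pairs: list[Pair]
    labels: np.ndarray
    X: np.ndarray


def build_training_set(
    acd: AssociationMatrix,
    s_c: SimilarityMatrix,
    s_d: SimilarityMatrix,
    seed: int = 0,
    negatives: Sequence[Pair] | None = None,
) -> TrainingSet:
    """Positives = all known associations; negatives sampled (or supplied)."""
    positives = acd.positive_pairs()
    if negatives is None:
        negatives = sample_negatives(acd, count=len(positives), seed=seed)
    pairs = list(positives) + list(negatives)
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    X = pair_descriptor_matrix(pairs, s_c, s_d)
    return TrainingSet(pairs=pairs, labels=labels, X=X)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    n: int | None = None,
    m: int | None = None,
) -> TrainedModel:
    """Fit the configured classifier on labeled descriptors.

    ``n`` and ``m`` (circRNA / disease counts) pin the expected descriptor
    split; if omitted they are inferred as (n_features, 0)-agnostic and only
    the total length is checked at scoring time.
    """
    config = config or ClassifierConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = _make_estimator(config)
    est.fit(np.asarray(X, dtype=float), y)
    total = X.shape[1]
    if n is None or m is None:
        n, m = total, 0
    if n + m != total:
        raise ValueError("n + m must equal the descriptor length")
    return TrainedModel(estimator=est, config=config, n=n, m=m)


def score_pairs(
    model: TrainedModel,
    pairs: Sequence[Pair],
    s_c: SimilarityMatrix,
    s_d: SimilarityMatrix,
) -> np.ndarray:
    """One finite real score per pair; higher = more likely an association."""
    X = pair_descriptor_matrix(pairs, s_c, s_d)
    return model.scores(X)


def rank_unknown_pairs(
    model: TrainedModel,
    acd: AssociationMatrix,
    s_c: SimilarityMatrix,
    s_d: SimilarityMatrix,
    k: int | None = None,
) -> pd.DataFrame:
    """Score every unknown cell and return the top-k candidate table.

    Sorted by descending score, ties broken by (circRNA index, disease
    index); ``k`` beyond the pool returns the full ranking. Columns:
    rank, circRNA, disease, score.
    """
    pool = acd.unknown_pairs()
    scores = score_pairs(model, pool, s_c, s_d)
    order = sorted(range(len(pool)), key=lambda t: (-scores[t], pool[t][0], pool[t][1]))
    if k is not None:
        order = order[: max(k, 1)]
    index = acd.index
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "circRNA": [index.circrna_ids[pool[t][0]] for t in order],
            "disease": [index.disease_names[pool[t][1]] for t in order],
            "score": [scores[t] for t in order],
        }
    )
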