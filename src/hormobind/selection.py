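"""F-score feature ranking and top-m selection.

The score of feature *i* is the classical one-way ANOVA F statistic

    F(i) = (ssb(i) / (K - 1)) / (ssw(i) / (N - K))

with ``ssb`` the between-class and ``ssw`` the within-class sum of squares,
``K`` the number of classes and ``N`` the number of samples. Larger F means
the feature separates the classes more strongly. Two degenerate cases get
explicit values: a feature that is constant within every class but differs
between classes (``ssw = 0``, ``ssb > 0``) is a perfect separator and is
scored ``+inf`` so it ranks first; a globally constant feature
(``ssw = ssb = 0``) carries no signal and is scored 0.

Selection metadata (encoder provenance, m, ordered indices, scores) is
serializable so the training-time selection can be replayed exactly on new
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoders import FeatureMatrix


@dataclass
class FScoreRanking:
    """Per-feature F scores and the descending-score feature order.

    Ties are broken by ascending feature index, so the order is a
    deterministic permutation of all feature indices.
    """

    scores: np.ndarray
    order: np.ndarray


@dataclass
class SelectionMeta:
    """Frozen record of a top-m selection, replayable on new data."""

    encoder_meta: dict
    n_features_in: int
    m: int
    indices: list[int]
    scores: list[float]
    feature_names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "encoder_meta": self.encoder_meta,
                "n_features_in": self.n_features_in,
                "m": self.m,
                "indices": self.indices,
                "scores": [("inf" if np.isinf(s) else s) for s in self.scores],
                "feature_names": self.feature_names,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SelectionMeta":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        raw = json.loads(text)
        return cls(
            encoder_meta=raw["encoder_meta"],
            n_features_in=raw["n_features_in"],
            m=raw["m"],
            indices=list(raw["indices"]),
            scores=[float("inf") if s == "inf" else float(s)
                    for s in raw["scores"]],
            feature_names=list(raw.get("feature_names", [])),
        )


def compute_f_scores(X: np.ndarray, y: np.ndarray) -> FScoreRanking:
    """Rank features by the one-way ANOVA F statistic.

    Requires at least two classes, each non-empty, and more samples than
    classes (so the within-class variance has positive degrees of freedom).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × features)")
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"row/label mismatch: {X.shape[0]} rows vs {y.shape[0]} labels")
    classes, counts = np.unique(y, return_counts=True)
    K = classes.size
    N = X.shape[0]
    if K < 2:
        raise ValueError("F-score needs at least two classes")
    if N <= K:
        raise ValueError(f"need more samples ({N}) than classes ({K})")

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for cls, n_c in zip(classes, counts):
        Xc = X[y == cls]
        mean_c = Xc.mean(axis=0)
        ssb += n_c * (mean_c - grand) ** 2
        ssw += ((Xc - mean_c) ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (ssb / (K - 1)) / (ssw / (N - K))
    zero_w = ssw == 0.0
    scores[zero_w & (ssb > 0.0)] = np.inf
    scores[zero_w & (ssb == 0.0)] = 0.0

    order = np.argsort(-scores, kind="stable")
    return FScoreRanking(scores=scores, order=order)


def select_top(
    ranking: FScoreRanking,
    m: int,
    X: FeatureMatrix,
) -> tuple[FeatureMatrix, SelectionMeta]:
    """Keep the top-m features in rank order; returns the reduced matrix
    and replayable selection metadata."""
    d = X.n_features
    if ranking.scores.shape[0] != d:
        raise ValueError("ranking does not match the feature matrix width")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m > d:
        raise ValueError(f"m={m} exceeds feature count {d}")
    idx = ranking.order[:m]
    meta = SelectionMeta(
        encoder_meta=dict(X.encoder_meta),
        n_features_in=d,
        m=m,
        indices=[int(i) for i in idx],
        scores=[float(ranking.scores[i]) for i in idx],
        feature_names=[X.feature_names[i] for i in idx],
    )
    reduced = FeatureMatrix(
        values=X.values[:, idx],
        feature_names=meta.feature_names,
        encoder_meta=dict(X.encoder_meta),
        sample_ids=list(X.sample_ids),
    )
    return reduced, meta


def apply_selection(meta: SelectionMeta, X_new: FeatureMatrix) -> FeatureMatrix:
    """Replay a training-time selection on new data: same columns, same order."""
    if meta.encoder_meta != X_new.encoder_meta:
        raise ValueError(
            f"encoder mismatch: selection was built on {meta.encoder_meta}, "
            f"input is {X_new.encoder_meta}")
    if X_new.n_features != meta.n_features_in:
        raise ValueError(
            f"feature count mismatch: selection expects "
            f"{meta.n_features_in}, input has {X_new.n_features}")
    idx = np.asarray(meta.indices, dtype=int)
    return FeatureMatrix(
        values=X_new.values[:, idx],
        feature_names=[X_new.feature_names[i] for i in idx],
        encoder_meta=dict(X_new.encoder_meta),
        sample_ids=list(X_new.sample_ids),
    )
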