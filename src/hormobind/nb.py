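"""Gaussian naive Bayes classifier.

The model factorizes the class posterior as

    P(y | x)  ∝  P(y) · ∏_i P(x_i | y)

with a univariate Gaussian per class and feature. Inputs here are
continuous composition/covariance descriptors, so the Gaussian likelihood
is the natural instantiation of the abstract per-feature factor. All
likelihood arithmetic is in the log domain and the posterior is recovered
with a softmax over per-class log scores, which both avoids underflow at
thousands of features and implements the division by P(x).

Per-class variances are maximum-likelihood (divide by the class count) and
floored at ``smoothing × max_f Var(x_f)`` plus an absolute 1e-12, because
selected sparse features are frequently constant within a class and a zero
variance would make the density degenerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianNaiveBayes:
    """Gaussian naive Bayes with a fit/predict_proba/predict contract.

    Any classifier exposing this trio (plus ``class_labels``) can stand in
    for it in the evaluation pipeline; that is the pluggable-classifier
    contract used for external baselines.
    """

    smoothing: float = 1e-9
    class_labels: np.ndarray | None = field(default=None, repr=False)
    priors: np.ndarray | None = field(default=None, repr=False)
    means: np.ndarray | None = field(default=None, repr=False)
    variances: np.ndarray | None = field(default=None, repr=False)

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-D with at least one feature")
        if X.shape[0] != y.shape[0]:
            raise ValueError("row/label length mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in X")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ValueError(
                f"class(es) {small.tolist()} have fewer than 2 samples; "
                "a variance cannot be estimated")

        C, d = classes.size, X.shape[1]
        means = np.empty((C, d))
        variances = np.empty((C, d))
        for ci, cls in enumerate(classes):
            Xc = X[y == cls]
            means[ci] = Xc.mean(axis=0)
            variances[ci] = Xc.var(axis=0)  # ML (divide by n_c)

        eps = self.smoothing * float(X.var(axis=0).max())
        floor = max(eps, 1e-12)
        self.class_labels = classes
        self.priors = counts / counts.sum()
        self.means = means
        self.variances = np.maximum(variances, floor)
        return self

    # -- inference ---------------------------------------------------------
    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise ValueError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"dimension mismatch: model has {self.means.shape[1]} "
                f"features, input has {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in X")
        return X

    def joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-sample, per-class ``log P(y) + Σ_i log N(x_i; μ, σ²)``."""
        X = self._check_fitted(X)
        n = X.shape[0]
        C = self.class_labels.size
        jll = np.empty((n, C))
        for ci in range(C):
            mu, var = self.means[ci], self.variances[ci]
            jll[:, ci] = np.log(self.priors[ci]) - 0.5 * np.sum(
                _LOG_2PI + np.log(var) + (X - mu) ** 2 / var, axis=1)
        return jll

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class posterior per sample; rows sum to 1 (softmax over classes)."""
        jll = self.joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Most probable class per sample; exact ties go to the earliest
        entry of ``class_labels`` (np.argmax takes the first maximum)."""
        jll = self.joint_log_likelihood(X)
        return self.class_labels[np.argmax(jll, axis=1)]

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        if self.means is None:
            raise ValueError("model is not fitted")
        return {
            "smoothing": self.smoothing,
            "class_labels": self.class_labels.tolist(),
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GaussianNaiveBayes":
        model = cls(smoothing=float(raw["smoothing"]))
        model.class_labels = np.asarray(raw["class_labels"])
        model.priors = np.asarray(raw["priors"], dtype=float)
        model.means = np.asarray(raw["means"], dtype=float)
        model.variances = np.asarray(raw["variances"], dtype=float)
        return model

    def to_json(self, path: str | Path | None = None) -> str:
        # repr-level float serialization round-trips bit-for-bit
        payload = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GaussianNaiveBayes":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))
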