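"""Binary-classification metrics, ROC/PRC curves, and K-fold cross-validation.

Metric formulas
---------------
From the confusion counts TP, FP, TN, FN:

    SN (sensitivity/recall) = TP / (TP + FN)
    SP (specificity)        = TN / (TN + FP)
    ACC                     = (TP + TN) / (TP + TN + FP + FN)
    precision               = TP / (TP + FP)
    F1                      = 2·precision·SN / (precision + SN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC, precision and F1 are defined as 0 when a denominator factor vanishes
(standard convention; keeps degenerate folds finite).

ROC is swept over the distinct score values in descending order, anchored
at (0,0) and (1,1); AUROC is the trapezoidal area, which equals the
Mann–Whitney concordance probability with ties counted 1/2. The
precision–recall curve uses the same sweep and AUPRC is the step-wise
(right-continuous) area Σ (R_t − R_{t−1})·P_t — trapezoidal interpolation
of precision is avoided because it overstates the area.

Cross-validation is stratified: each class is shuffled with a seeded
generator and dealt round-robin into K folds, so fold class balance is
within one sample of the dataset's. Feature selection runs inside each
training fold by default; ``selection_mode="pre-cv"`` instead selects once
on the full dataset before splitting, reproducing protocols that reduce
dimensionality ahead of CV (optimistically biased; see docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Callable

import numpy as np

from .encoders import FeatureMatrix, encode_dataset
from .io import DataError, LabeledDataset, POSITIVE
from .nb import GaussianNaiveBayes
from .selection import apply_selection, compute_f_scores, select_top

METRIC_NAMES = ("SN", "SP", "ACC", "precision", "F1", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


def confusion(y_true, y_pred, positive=POSITIVE) -> ConfusionCounts:
    """Count TP/FP/TN/FN with respect to the given positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"more than two distinct labels: {sorted(labels)}")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Scalar metric set {SN, SP, ACC, precision, F1, MCC} from counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sn = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    sp = c.TN / (c.TN + c.FP) if c.TN + c.FP else 0.0
    acc = (c.TP + c.TN) / c.total
    prec = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    f1 = 2 * prec * sn / (prec + sn) if prec + sn else 0.0
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = (c.TP * c.TN - c.FP * c.FN) / sqrt(denom) if denom else 0.0
    return {"SN": sn, "SP": sp, "ACC": acc, "precision": prec,
            "F1": f1, "MCC": mcc}


def _sweep(y_true, scores, positive):
    """Cumulative TP/FP at each distinct descending score threshold."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores length mismatch")
    pos = (y_true == positive).astype(int)
    P = int(pos.sum())
    N = int(pos.size - P)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(pos[order])
    fps = np.cumsum(1 - pos[order])
    # keep the last index of each tied-score run
    last = np.nonzero(np.diff(sorted_scores, append=np.nan))[0]
    return tps[last], fps[last], P, N


def roc_points(y_true, scores, positive=POSITIVE
               ) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR) from (0,0) to (1,1) and trapezoidal AUROC."""
    tps, fps, P, N = _sweep(y_true, scores, positive)
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present")
    tpr = np.concatenate(([0.0], tps / P))
    fpr = np.concatenate(([0.0], fps / N))
    auroc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auroc


def prc_points(y_true, scores, positive=POSITIVE
               ) -> tuple[np.ndarray, float]:
    """Precision–recall points over descending thresholds and step-rule AUPRC."""
    tps, fps, P, _ = _sweep(y_true, scores, positive)
    if P == 0:
        raise ValueError("PRC needs at least one positive sample")
    recall = tps / P
    precision = tps / (tps + fps)
    dr = np.diff(recall, prepend=0.0)
    auprc = float(np.sum(dr * precision))
    return np.column_stack([recall, precision]), auprc


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Fold id per sample: each class is shuffled (seeded) and dealt
    round-robin, so every sample lands in exactly one test fold."""
    y = np.asarray(y)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"K={K} exceeds the size of the smallest class ({counts.min()})")
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.shape[0], dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % K
    return assignment


@dataclass
class EvaluationReport:
    """Per-fold and pooled cross-validation results.

    ``pooled`` metrics come from confusion counts summed over folds (the
    headline numbers); ``fold_mean``/``fold_sd`` aggregate the per-fold
    metrics instead, since averaging over folds is the other common
    convention. ROC/PRC are computed on the pooled held-out scores.
    """

    K: int
    seed: int
    config: dict
    fold_assignment: list[int]
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[dict[str, float]]
    pooled_counts: ConfusionCounts
    pooled: dict[str, float]
    fold_mean: dict[str, float]
    fold_sd: dict[str, float]
    auroc: float
    auprc: float
    roc: np.ndarray = field(repr=False)
    prc: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "config": self.config,
            "fold_assignment": list(map(int, self.fold_assignment)),
            "fold_counts": [vars(c) for c in self.fold_counts],
            "fold_metrics": self.fold_metrics,
            "pooled_counts": vars(self.pooled_counts),
            "pooled": self.pooled,
            "fold_mean": self.fold_mean,
            "fold_sd": self.fold_sd,
            "AUROC": self.auroc,
            "AUPRC": self.auprc,
            "roc": self.roc.tolist(),
            "prc": self.prc.tolist(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def write_tables(self, directory: str | Path) -> None:
        """Export per-fold/pooled metric TSVs and ROC/PRC point lists."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with (directory / "folds.tsv").open("w") as fh:
            fh.write("fold\tTP\tFP\tTN\tFN\t" + "\t".join(METRIC_NAMES) + "\n")
            for k, (c, m) in enumerate(zip(self.fold_counts,
                                           self.fold_metrics)):
                fh.write(f"{k}\t{c.TP}\t{c.FP}\t{c.TN}\t{c.FN}\t"
                         + "\t".join(f"{m[n]:.6f}" for n in METRIC_NAMES)
                         + "\n")
        with (directory / "pooled.tsv").open("w") as fh:
            fh.write("metric\tpooled\tfold_mean\tfold_sd\n")
            for n in METRIC_NAMES:
                fh.write(f"{n}\t{self.pooled[n]:.6f}\t{self.fold_mean[n]:.6f}"
                         f"\t{self.fold_sd[n]:.6f}\n")
            fh.write(f"AUROC\t{self.auroc:.6f}\t\t\n")
            fh.write(f"AUPRC\t{self.auprc:.6f}\t\t\n")
        np.savetxt(directory / "roc.tsv", self.roc, delimiter="\t",
                   header="FPR\tTPR", comments="")
        np.savetxt(directory / "prc.tsv", self.prc, delimiter="\t",
                   header="recall\tprecision", comments="")


def kfold_cv(
    dataset: LabeledDataset,
    *,
    encoder: str = "kmer",
    encoder_params: dict | None = None,
    pssm_source=None,
    m: int | None = 250,
    selection_mode: str = "within-fold",
    classifier_factory: Callable[[], object] | None = None,
    K: int = 10,
    seed: int = 42,
) -> EvaluationReport:
    """Stratified K-fold cross-validation of the encode→select→classify
    pipeline on a labeled dataset.

    ``m=None`` disables feature selection. ``classifier_factory`` must
    return a fresh object with fit/predict_proba/predict and
    ``class_labels``; the default is :class:`GaussianNaiveBayes`.
    """
    if selection_mode not in ("within-fold", "pre-cv"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    dataset.require_both_classes()
    if classifier_factory is None:
        classifier_factory = GaussianNaiveBayes

    encoder_params = encoder_params or {}
    X, y = encode_dataset(dataset, encoder=encoder,
                          pssm_source=pssm_source, **encoder_params)
    if m is not None and m > X.n_features:
        raise ValueError(f"m={m} exceeds feature count {X.n_features}")
    assignment = stratified_folds(y, K, seed)

    pre_meta = None
    if m is not None and selection_mode == "pre-cv":
        _, pre_meta = select_top(compute_f_scores(X.values, y), m, X)

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[dict[str, float]] = []
    pooled_scores = np.empty(len(y), dtype=float)
    pooled_pred = np.empty(len(y), dtype=y.dtype)
    for k in range(K):
        test = assignment == k
        train = ~test
        if pre_meta is not None:
            meta = pre_meta
        elif m is not None:
            Xtr = FeatureMatrix(X.values[train], X.feature_names,
                                dict(X.encoder_meta),
                                [X.sample_ids[i] for i in np.flatnonzero(train)])
            _, meta = select_top(compute_f_scores(Xtr.values, y[train]),
                                 m, Xtr)
        else:
            meta = None
        if meta is not None:
            idx = np.asarray(meta.indices, dtype=int)
            Xtr_v, Xte_v = X.values[train][:, idx], X.values[test][:, idx]
        else:
            Xtr_v, Xte_v = X.values[train], X.values[test]

        clf = classifier_factory().fit(Xtr_v, y[train])
        proba = clf.predict_proba(Xte_v)
        pos_col = int(np.flatnonzero(clf.class_labels == POSITIVE)[0])
        pooled_scores[test] = proba[:, pos_col]
        pred = clf.predict(Xte_v)
        pooled_pred[test] = pred
        c = confusion(y[test], pred)
        fold_counts.append(c)
        fold_metrics.append(metrics(c))

    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for c in fold_counts:
        pooled_counts = pooled_counts + c
    if pooled_counts.total != len(y):
        raise AssertionError("folds do not partition the dataset")
    pooled = metrics(pooled_counts)
    fold_mean = {n: float(np.mean([fm[n] for fm in fold_metrics]))
                 for n in METRIC_NAMES}
    fold_sd = {n: float(np.std([fm[n] for fm in fold_metrics]))
               for n in METRIC_NAMES}
    roc, auroc = roc_points(y, pooled_scores)
    prc, auprc = prc_points(y, pooled_scores)

    config = {
        "encoder": encoder,
        "encoder_params": dict(X.encoder_meta),
        "m": m,
        "selection_mode": selection_mode,
        "classifier": type(classifier_factory()).__name__,
        "K": K,
        "seed": seed,
    }
    return EvaluationReport(
        K=K, seed=seed, config=config,
        fold_assignment=assignment.tolist(),
        fold_counts=fold_counts, fold_metrics=fold_metrics,
        pooled_counts=pooled_counts, pooled=pooled,
        fold_mean=fold_mean, fold_sd=fold_sd,
        auroc=auroc, auprc=auprc, roc=roc, prc=prc,
        scores=pooled_scores,
    )
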