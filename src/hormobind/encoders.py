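"""Fixed-length feature encodings of protein sequences.

Three encoders are provided:

``kmer``
    Frequency of every length-``k`` word over the 20-letter alphabet in the
    ``L - k + 1`` overlapping windows of the sequence; dimension ``20**k``
    (8000 for k=3, 400 for k=2). Frequencies, not counts, so the vector sums
    to 1 and is length-independent.

``dr``
    Distance-based residue counts: the 20 single-residue counts (distance 0)
    followed, for each distance ``d`` in ``1..d_max``, by the 400 counts of
    ordered residue pairs ``(R_i, R_{i+d})``; dimension ``20 + 400*d_max``.
    Raw occurrence counts.

``cc_pssm``
    Cross-covariance of PSSM columns: for each ordered pair of *distinct*
    residue columns (380 pairs) and each lag in ``1..lag_max``,

        CC(i1, i2, lag) = sum_{j=1}^{L-lag}
            (S[j, i1] - mean(S[:, i1])) * (S[j+lag, i2] - mean(S[:, i2]))
            / (L - lag)

    with column means taken over all L positions; dimension ``380*lag_max``,
    ordered lag-major then by pair in row-major (i1, i2) order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io import (ALPHABET, DataError, LabeledDataset, Pssm, SequenceRecord,
                 read_pssm)

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class FeatureMatrix:
    """Samples × named features with encoder provenance.

    ``encoder_meta`` records the encoder name and its parameters so a
    selection or model fitted on one matrix can refuse incompatible input.
    """

    values: np.ndarray
    feature_names: list[str]
    encoder_meta: dict
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples × features)")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path, labels: np.ndarray | None = None) -> None:
        """Export as TSV: first column sample id, optional label, then features."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        if labels is not None:
            df.insert(1, "label", np.asarray(labels))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, encoder_meta: dict | None = None
                 ) -> tuple["FeatureMatrix", np.ndarray | None]:
        df = pd.read_csv(path, sep="\t")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        ids = df.pop("sample_id").astype(str).tolist()
        fm = cls(values=df.to_numpy(dtype=float),
                 feature_names=list(df.columns),
                 encoder_meta=encoder_meta or {},
                 sample_ids=ids)
        return fm, labels


def kmer_feature_names(k: int) -> list[str]:
    """All length-k words in lexicographic order over the canonical alphabet."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def encode_kmer(seq: SequenceRecord, k: int = 3, *,
                allow_large_k: bool = False) -> np.ndarray:
    """k-mer frequency vector of length ``20**k``.

    Entries are window counts divided by the number of overlapping windows
    ``L - k + 1``; they sum to 1. ``k`` is limited to 1..3 (dimensionality
    blows up beyond that) unless ``allow_large_k`` is set.
    """
    if k < 1 or (k > 3 and not allow_large_k):
        raise ValueError(f"k={k} outside 1..3 (set allow_large_k to override)")
    L = len(seq)
    if L < k:
        raise DataError(f"record {seq.id!r}: length {L} < k={k}")
    vec = np.zeros(20 ** k)
    n_windows = L - k + 1
    # base-20 rolling index over the window
    idx = 0
    for aa in seq.residues[: k - 1]:
        idx = idx * 20 + _INDEX[aa]
    mod = 20 ** (k - 1)
    for aa in seq.residues[k - 1:]:
        idx = (idx % mod) * 20 + _INDEX[aa]
        vec[idx] += 1.0
    return vec / n_windows


def dr_feature_names(d_max: int) -> list[str]:
    names = [f"dr:d0:{aa}" for aa in ALPHABET]
    for d in range(1, d_max + 1):
        names.extend(f"dr:d{d}:{a}{b}" for a in ALPHABET for b in ALPHABET)
    return names


def encode_dr(seq: SequenceRecord, d_max: int = 3) -> np.ndarray:
    """Distance-based residue count vector of length ``20 + 400*d_max``."""
    if d_max < 1:
        raise ValueError(f"d_max must be >= 1, got {d_max}")
    L = len(seq)
    if L <= d_max:
        raise DataError(f"record {seq.id!r}: length {L} <= d_max={d_max}")
    vec = np.zeros(20 + 400 * d_max)
    codes = np.fromiter((_INDEX[aa] for aa in seq.residues), dtype=np.intp,
                        count=L)
    np.add.at(vec, codes, 1.0)
    for d in range(1, d_max + 1):
        pair_idx = 20 + 400 * (d - 1) + codes[:-d] * 20 + codes[d:]
        np.add.at(vec, pair_idx, 1.0)
    return vec


def cc_feature_names(lag_max: int) -> list[str]:
    names = []
    for lag in range(1, lag_max + 1):
        for a in ALPHABET:
            for b in ALPHABET:
                if a != b:
                    names.append(f"cc:lag{lag}:{a}-{b}")
    return names


def encode_cc_pssm(pssm: Pssm, lag_max: int = 2) -> np.ndarray:
    """Cross-covariance vector of length ``380*lag_max`` from an L×20 PSSM."""
    if lag_max < 1:
        raise ValueError(f"lag_max must be >= 1, got {lag_max}")
    L = len(pssm)
    if L <= lag_max:
        raise DataError(
            f"PSSM {pssm.sequence_id!r}: length {L} <= lag_max={lag_max}")
    centered = pssm.scores - pssm.scores.mean(axis=0, keepdims=True)
    off_diag = ~np.eye(20, dtype=bool)
    blocks = []
    for lag in range(1, lag_max + 1):
        cc = centered[:L - lag].T @ centered[lag:] / (L - lag)  # 20×20
        blocks.append(cc[off_diag])  # row-major (i1, i2), i1 != i2
    return np.concatenate(blocks)


_ENCODERS: dict[str, dict] = {
    "kmer": {"params": ("k",), "defaults": {"k": 3}},
    "dr": {"params": ("d_max",), "defaults": {"d_max": 3}},
    "cc_pssm": {"params": ("lag_max",), "defaults": {"lag_max": 2}},
}


def encoder_dimension(name: str, **params) -> int:
    if name == "kmer":
        return 20 ** params.get("k", 3)
    if name == "dr":
        return 20 + 400 * params.get("d_max", 3)
    if name == "cc_pssm":
        return 380 * params.get("lag_max", 2)
    raise ValueError(f"unknown encoder {name!r}")


PssmSource = Mapping[str, Pssm] | str | Path | Callable[[str], Pssm]


def _resolve_pssm(source: PssmSource, record_id: str) -> Pssm:
    if callable(source):
        return source(record_id)
    if isinstance(source, Mapping):
        if record_id not in source:
            raise DataError(f"no PSSM available for record {record_id!r}")
        return source[record_id]
    directory = Path(source)
    for suffix in (".pssm", ".tsv", ".txt"):
        candidate = directory / f"{record_id}{suffix}"
        if candidate.exists():
            return read_pssm(candidate, sequence_id=record_id)
    raise DataError(f"no PSSM file for record {record_id!r} under {directory}")


def encode_dataset(
    dataset: LabeledDataset,
    encoder: str = "kmer",
    pssm_source: PssmSource | None = None,
    **params,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Encode every record; returns a FeatureMatrix and the aligned label array.

    Per-record encoder failures are re-raised with the offending record id.
    """
    if encoder not in _ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}; "
                         f"choose from {sorted(_ENCODERS)}")
    if len(dataset) == 0:
        raise DataError("cannot encode an empty dataset")
    spec = _ENCODERS[encoder]
    resolved = dict(spec["defaults"])
    resolved.update({k: v for k, v in params.items() if v is not None})
    extra = set(resolved) - set(spec["params"])
    if extra:
        raise ValueError(f"encoder {encoder!r} does not accept {sorted(extra)}")

    if encoder == "kmer":
        names = kmer_feature_names(resolved["k"])
        rows = [encode_kmer(r, **resolved) for r in dataset.records]
    elif encoder == "dr":
        names = dr_feature_names(resolved["d_max"])
        rows = [encode_dr(r, **resolved) for r in dataset.records]
    else:  # cc_pssm
        if pssm_source is None:
            raise DataError("cc_pssm encoding requires a PSSM source")
        names = cc_feature_names(resolved["lag_max"])
        rows = []
        for r in dataset.records:
            pssm = _resolve_pssm(pssm_source, r.id)
            if len(pssm) != len(r):
                raise DataError(
                    f"PSSM for {r.id!r} has {len(pssm)} rows but the "
                    f"sequence has {len(r)} residues")
            rows.append(encode_cc_pssm(pssm, **resolved))

    labels = np.array([r.label for r in dataset.records], dtype=int)
    fm = FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        encoder_meta={"encoder": encoder, **resolved},
        sample_ids=[r.id for r in dataset.records],
    )
    return fm, labels
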