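"""Sequence and PSSM input/output.

FASTA reading goes through Bio.SeqIO; records are validated against the
20-letter standard amino-acid alphabet. Sequences containing unknown
residue codes (``X``, ``Z``, ``B``, ...) are either rejected (``strict``)
or dropped (``skip``) — never recoded, because downstream composition
features have no sensible value for an ambiguous residue.

PSSM files are accepted in two dialects: the first log-odds block of
PSI-BLAST ASCII output, and a native tab-separated format (one header
line of 20 residue letters, then one row of reals per sequence position).
Columns are re-ordered to the canonical alphabet on read, so downstream
code never sees file-specific column order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, fixed column/feature order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)
_ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

POSITIVE = 1
NEGATIVE = 0


class DataError(ValueError):
    """Malformed or invalid input data (bad FASTA/PSSM, empty class, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One validated amino-acid sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    residues : str
        Sequence over :data:`ALPHABET`, length >= 1.
    label : int or None
        ``POSITIVE`` (1), ``NEGATIVE`` (0) or ``None`` for unlabeled.
    """

    id: str
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence identifier must be non-empty")
        if not self.residues:
            raise DataError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise DataError(
                f"record {self.id!r}: residue(s) outside the 20-letter "
                f"alphabet: {''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Pssm:
    """Position-specific scoring matrix for one sequence.

    ``scores`` has one row per sequence position and exactly 20 columns in
    canonical alphabet order.
    """

    sequence_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise DataError(
                f"PSSM for {self.sequence_id!r}: expected L×20 matrix, "
                f"got shape {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise DataError(f"PSSM for {self.sequence_id!r}: no rows")
        if not np.all(np.isfinite(scores)):
            raise DataError(f"PSSM for {self.sequence_id!r}: non-finite scores")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class LabeledDataset:
    """Ordered collection of labeled records with per-class counts."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.label not in (POSITIVE, NEGATIVE):
                raise DataError(f"record {rec.id!r} is unlabeled")
            if rec.id in seen:
                raise DataError(f"duplicate identifier {rec.id!r} in dataset")
            seen.add(rec.id)

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE)

    def __len__(self) -> int:
        return len(self.records)

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise DataError(
                "dataset must contain at least one record of each class "
                f"(positives={self.n_positive}, negatives={self.n_negative})"
            )


def _normalize_residues(raw: str) -> str:
    """Upper-case and strip a single terminal stop character ('*')."""
    s = str(raw).strip().upper()
    if s.endswith("*"):
        s = s[:-1]
    return s


def read_fasta(
    path: str | Path,
    policy: str = "strict",
    label: int | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    ``policy='strict'`` raises on any residue outside the alphabet;
    ``policy='skip'`` drops offending records and logs how many were
    dropped. There is no masking/recoding mode.
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown policy {policy!r}; use 'strict' or 'skip'")
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dropped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DataError(f"duplicate identifier {entry.id!r} in {path}")
        seen.add(entry.id)
        residues = _normalize_residues(str(entry.seq))
        bad = sorted(set(residues) - _ALPHABET_SET)
        if bad or not residues:
            if policy == "strict":
                what = f"invalid residue(s) {''.join(bad)!r}" if bad else "empty sequence"
                raise DataError(f"record {entry.id!r} in {path}: {what}")
            dropped += 1
            logger.warning("dropping record %r (%s)", entry.id,
                           f"invalid residues {''.join(bad)}" if bad else "empty")
            continue
        records.append(SequenceRecord(id=entry.id, residues=residues, label=label))
    if dropped:
        logger.info("read_fasta(%s): kept %d records, dropped %d", path,
                    len(records), dropped)
    if not records and not dropped:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.residues), width):
                fh.write(rec.residues[start:start + width] + "\n")


def load_labeled_dataset(
    positives: str | Path,
    negatives: str | Path,
    policy: str = "strict",
) -> LabeledDataset:
    """Assemble a two-class dataset from positive and negative FASTA files."""
    pos = read_fasta(positives, policy=policy, label=POSITIVE)
    neg = read_fasta(negatives, policy=policy, label=NEGATIVE)
    if not pos:
        raise DataError(f"empty class: no valid records in {positives}")
    if not neg:
        raise DataError(f"empty class: no valid records in {negatives}")
    overlap = {r.id for r in pos} & {r.id for r in neg}
    if overlap:
        raise DataError(
            "identifier(s) present in both classes (ambiguous label): "
            + ", ".join(sorted(overlap))
        )
    ds = LabeledDataset(records=pos + neg)
    logger.info("loaded dataset: %d positives, %d negatives",
                ds.n_positive, ds.n_negative)
    return ds


# ---------------------------------------------------------------------------
# PSSM I/O
# ---------------------------------------------------------------------------

def _reorder_columns(matrix: np.ndarray, header: list[str],
                     context: str) -> np.ndarray:
    """Re-order score columns from file order to canonical alphabet order."""
    if sorted(header) != sorted(ALPHABET):
        unknown = [h for h in header if h not in _ALPHABET_SET]
        raise DataError(
            f"{context}: residue column header must be a permutation of the "
            f"20-letter alphabet (unknown/duplicated: {unknown or header})"
        )
    perm = [header.index(aa) for aa in ALPHABET]
    return matrix[:, perm]


def _parse_native_pssm(lines: list[str], context: str) -> np.ndarray:
    header = lines[0].split()
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 20:
            raise DataError(
                f"{context}, line {lineno}: expected 20 score fields, "
                f"got {len(fields)}"
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise DataError(f"{context}, line {lineno}: non-numeric score "
                            f"({exc})") from None
    if not rows:
        raise DataError(f"{context}: no score rows")
    return _reorder_columns(np.array(rows, dtype=float), header, context)


def _parse_psiblast_pssm(lines: list[str], context: str) -> np.ndarray:
    """Parse the first (log-odds) 20-column block of PSI-BLAST ASCII output.

    The header row carries 40 residue letters (20 log-odds + 20 percentage
    columns) or 20 in reduced output; only the first 20 are used. Data rows
    are ``pos residue s1..s20 ...``; trailing percentage/information columns
    are ignored.
    """
    header: list[str] | None = None
    rows = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if header is None:
            if len(fields) >= 20 and all(
                len(f) == 1 and f.isalpha() for f in fields[:20]
            ):
                header = [f.upper() for f in fields[:20]]
            continue
        if not fields:
            if rows:
                break  # end of matrix block
            continue
        if not fields[0].isdigit():
            break
        if len(fields) < 22:
            raise DataError(
                f"{context}, line {lineno}: expected position, residue and "
                f"20 scores, got {len(fields)} fields"
            )
        try:
            rows.append([float(x) for x in fields[2:22]])
        except ValueError as exc:
            raise DataError(f"{context}, line {lineno}: non-numeric score "
                            f"({exc})") from None
    if header is None:
        raise DataError(f"{context}: no residue column header found")
    if not rows:
        raise DataError(f"{context}: no score rows")
    return _reorder_columns(np.array(rows, dtype=float), header, context)


def read_pssm(path: str | Path, sequence_id: str | None = None) -> Pssm:
    """Read a PSSM from PSI-BLAST ASCII output or the native TSV dialect.

    The dialect is sniffed: a first non-empty line consisting of exactly
    20 single residue letters marks the native format; anything else is
    parsed as PSI-BLAST ASCII (first log-odds block only).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"PSSM file not found: {path}")
    lines = path.read_text().splitlines()
    stripped = [ln for ln in lines if ln.strip()]
    if not stripped:
        raise DataError(f"empty PSSM file: {path}")
    first = stripped[0].split()
    context = str(path)
    if len(first) == 20 and all(len(f) == 1 and f.isalpha() for f in first):
        scores = _parse_native_pssm(stripped, context)
    else:
        scores = _parse_psiblast_pssm(lines, context)
    return Pssm(sequence_id=sequence_id or path.stem, scores=scores)


def write_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write a PSSM in the native TSV dialect (canonical column order)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(ALPHABET) + "\n")
        for row in pssm.scores:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def class_counts(records: list[SequenceRecord]) -> Counter:
    return Counter(r.label for r in records)
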