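"""Synthetic two-class sequence datasets with controllable separation.

The generator emulates the statistical structure the pipeline's features
respond to: two classes whose residue compositions diverge. Each class
draws residues i.i.d. from a profile obtained by interpolating between the
uniform composition and a class-specific "enriched" profile:

    p_class(δ) = (1 − δ) · uniform + δ · enriched_class

δ = 0 makes the classes identical (no signal, CV accuracy should sit at
chance); δ = 1 gives maximal divergence. The default enriched profiles each
put 0.15 on four class-specific residues (positive: A, K, L, S; negative:
D, G, P, V) and spread the remainder uniformly — composition-level signal
that k-mer and DR features pick up directly, making separability
analytically controllable. An optional first-order Markov transition matrix
supports correlated compositions.

Synthetic PSSMs place a signal of strength σ at the true residue's column
in each row and standard Gaussian noise everywhere, mimicking the
conservation signal of profile-search PSSMs at an adjustable
signal-to-noise ratio.

Everything is a pure function of (spec, seed): one named generator per
call, no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (ALPHABET, DataError, LabeledDataset, NEGATIVE, POSITIVE,
                 Pssm, SequenceRecord, write_fasta, write_pssm)

#: Residues enriched in the two default class profiles.
POSITIVE_ENRICHED = "AKLS"
NEGATIVE_ENRICHED = "DGPV"
_ENRICHED_MASS = 0.15  # per enriched residue at δ=1


@dataclass(frozen=True)
class ClassProfile:
    """Residue emission distribution, optionally with Markov transitions."""

    residue_probs: np.ndarray
    transitions: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.residue_probs, dtype=float)
        if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise DataError("residue_probs must be a length-20 distribution")
        object.__setattr__(self, "residue_probs", p)
        if self.transitions is not None:
            T = np.asarray(self.transitions, dtype=float)
            if (T.shape != (20, 20) or np.any(T < 0)
                    or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12)):
                raise DataError("transitions must be a 20×20 stochastic matrix")
            object.__setattr__(self, "transitions", T)


def enriched_profile(enriched: str, delta: float) -> ClassProfile:
    """Interpolate uniform composition toward a profile enriched in the
    given residues; ``delta`` in [0, 1]."""
    if not 0.0 <= delta <= 1.0:
        raise DataError(f"delta must be in [0, 1], got {delta}")
    idx = [ALPHABET.index(aa) for aa in enriched]
    target = np.full(20, (1.0 - _ENRICHED_MASS * len(idx)) / (20 - len(idx)))
    target[idx] = _ENRICHED_MASS
    probs = (1.0 - delta) * np.full(20, 0.05) + delta * target
    return ClassProfile(residue_probs=probs / probs.sum())


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic benchmark; see module docstring."""

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (80, 300)
    delta: float = 0.6
    seed: int = 42
    positive_profile: ClassProfile | None = None
    negative_profile: ClassProfile | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise DataError("n_pos and n_neg must be >= 1")
        lmin, lmax = self.length_range
        if lmin < 3 or lmax < lmin:
            raise DataError("length range must satisfy 3 <= Lmin <= Lmax")
        if not 0.0 <= self.delta <= 1.0:
            raise DataError(f"delta must be in [0, 1], got {self.delta}")

    def profiles(self) -> tuple[ClassProfile, ClassProfile]:
        pos = self.positive_profile or enriched_profile(POSITIVE_ENRICHED,
                                                        self.delta)
        neg = self.negative_profile or enriched_profile(NEGATIVE_ENRICHED,
                                                        self.delta)
        return pos, neg

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "length_range": list(self.length_range),
            "delta": self.delta, "seed": self.seed,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticSpec":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        raw = json.loads(text)
        return cls(n_pos=raw["n_pos"], n_neg=raw["n_neg"],
                   length_range=tuple(raw["length_range"]),
                   delta=raw["delta"], seed=raw["seed"])


def reference_benchmark_spec(seed: int = 42) -> SyntheticSpec:
    """The frozen separable benchmark: 100+100 sequences, L ∈ [80, 300],
    δ = 0.6 between the two default 4-residue-enriched profiles."""
    return SyntheticSpec(n_pos=100, n_neg=100, length_range=(80, 300),
                         delta=0.6, seed=seed)


def sample_sequence(profile: ClassProfile, L: int,
                    rng: np.random.Generator, *,
                    record_id: str = "synthetic",
                    label: int | None = None) -> SequenceRecord:
    """Draw one sequence of length L from the profile (i.i.d., or a Markov
    chain when transitions are given)."""
    if L < 1:
        raise DataError(f"sequence length must be >= 1, got {L}")
    alpha = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    if profile.transitions is None:
        codes = rng.choice(20, size=L, p=profile.residue_probs)
    else:
        codes = np.empty(L, dtype=int)
        codes[0] = rng.choice(20, p=profile.residue_probs)
        for j in range(1, L):
            codes[j] = rng.choice(20, p=profile.transitions[codes[j - 1]])
    residues = alpha[codes].tobytes().decode()
    return SequenceRecord(id=record_id, residues=residues, label=label)


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate the labeled dataset described by the spec; identifiers
    encode class and index (pos_0001, neg_0001, ...)."""
    rng = np.random.default_rng(spec.seed)
    pos_profile, neg_profile = spec.profiles()
    lmin, lmax = spec.length_range
    records: list[SequenceRecord] = []
    for prefix, n, profile, label in (
        ("pos", spec.n_pos, pos_profile, POSITIVE),
        ("neg", spec.n_neg, neg_profile, NEGATIVE),
    ):
        for i in range(n):
            L = int(rng.integers(lmin, lmax + 1))
            records.append(sample_sequence(
                profile, L, rng, record_id=f"{prefix}_{i + 1:04d}",
                label=label))
    return LabeledDataset(records=records)


def generate_pssm(seq: SequenceRecord, signal: float,
                  rng: np.random.Generator) -> Pssm:
    """Synthetic PSSM: row j = ``signal`` at the column of residue R_j plus
    N(0, 1) noise in every cell; shape L×20."""
    L = len(seq)
    scores = rng.normal(0.0, 1.0, size=(L, 20))
    cols = [ALPHABET.index(aa) for aa in seq.residues]
    scores[np.arange(L), cols] += signal
    return Pssm(sequence_id=seq.id, scores=scores)


def write_benchmark(spec: SyntheticSpec, directory: str | Path, *,
                    pssm_signal: float | None = None) -> dict:
    """Materialize a spec as FASTA files (plus optional PSSM TSVs) so the
    synthetic data flows through the same readers as real data. Returns a
    manifest dict (also written as manifest.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(spec)
    pos = [r for r in ds.records if r.label == POSITIVE]
    neg = [r for r in ds.records if r.label == NEGATIVE]
    write_fasta(pos, directory / "positives.fasta")
    write_fasta(neg, directory / "negatives.fasta")
    manifest = {
        "spec": json.loads(spec.to_json()),
        "n_pos": len(pos), "n_neg": len(neg),
        "files": ["positives.fasta", "negatives.fasta"],
    }
    if pssm_signal is not None:
        pssm_dir = directory / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(spec.seed + 1)
        for rec in ds.records:
            write_pssm(generate_pssm(rec, pssm_signal, rng),
                       pssm_dir / f"{rec.id}.pssm")
        manifest["pssm_signal"] = pssm_signal
        manifest["files"].append("pssm/")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
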