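"""Sequence input/output, validation, dataset-preparation filters and splits.

Transcript sequences arrive as FASTA (DNA or RNA alphabet); labels arrive
either as a two-column TSV (id, label) or implicitly via separate
positive/negative FASTA files.  The preparation pipeline mirrors common
circRNA benchmark construction: drop short transcripts (< 200 nt), collapse
near-duplicate sequences at 80% identity, then split into train/test
stratified by class.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

VALID_CHARS = frozenset("ACGTUN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically malformed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U,N}."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled transcript sequence.

    label is 1 for the circRNA-like positive class, 0 for the negative
    (lncRNA-like) class, or None when unlabeled.  Sequences are stored
    uppercase; a record never mixes T and U.
    """

    id: str
    seq: str
    label: int | None = None
    source: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_rna(self) -> bool:
        return "U" in self.seq


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test id lists covering all records."""

    train: tuple[str, ...]
    test: tuple[str, ...]


def _validate_seq(rec_id: str, seq: str) -> str:
    seq = "".join(seq.split()).upper()
    bad = set(seq) - VALID_CHARS
    if bad:
        raise SequenceValidationError(
            f"record {rec_id!r}: invalid characters {sorted(bad)} "
            "(allowed: A,C,G,T,U,N)"
        )
    if "U" in seq and "T" in seq:
        # canonicalize mixed-alphabet records to DNA
        seq = seq.replace("U", "T")
    return seq


def read_fasta(path: str | Path, label: int | None = None,
               source: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order.

    Uppercases sequences and strips whitespace.  Raises FastaParseError on
    malformed headers or an empty file, SequenceValidationError on invalid
    characters (the offending record id is named).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    cur_id: str | None = None
    cur_chunks: list[str] = []
    src = source if source is not None else path.name
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    records.append(SequenceRecord(
                        cur_id, _validate_seq(cur_id, "".join(cur_chunks)),
                        label, src))
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                cur_id = header.split()[0]
                cur_chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header")
                cur_chunks.append(line.strip())
    if cur_id is None:
        raise FastaParseError(f"{path}: no FASTA entries found")
    records.append(SequenceRecord(
        cur_id, _validate_seq(cur_id, "".join(cur_chunks)), label, src))
    for rec in records:
        if not rec.seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) TSV; labels must be 0 or 1."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
            if lineno == 1 and parts[1].lower() in {"label", "class", "y"}:
                continue
            rec_id, lab = parts[0], parts[1]
            if lab not in {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            labels[rec_id] = int(lab)
    return labels


def attach_labels(records: Sequence[SequenceRecord],
                  labels: dict[str, int]) -> list[SequenceRecord]:
    """Return records with labels looked up by id; missing ids raise KeyError."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise KeyError(f"no label for record {rec.id!r}")
        out.append(replace(rec, label=labels[rec.id]))
    return out


def filter_min_length(records: Sequence[SequenceRecord],
                      min_len: int = 200) -> list[SequenceRecord]:
    """Drop sequences shorter than min_len nt (strict: length == min_len kept)."""
    return [r for r in records if len(r.seq) >= min_len]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)
            if "N" not in seq[i:i + k]}


def kmer_containment_identity(a: str, b: str, k: int = 5) -> float:
    """Shared k-mers divided by the k-mer count of the shorter sequence."""
    sa, sb = _kmer_set(a, k), _kmer_set(b, k)
    if len(a) > len(b):
        sa, sb = sb, sa
    if not sa:
        return 0.0
    return len(sa & sb) / len(sa)


def reduce_redundancy(records: Sequence[SequenceRecord],
                      identity_threshold: float = 0.8,
                      k: int = 5) -> list[SequenceRecord]:
    """Greedy longest-first redundancy reduction at a k-mer identity threshold.

    Records are visited longest first; a record is dropped when its k-mer
    containment identity with any already-retained record exceeds the
    threshold.  Cluster representatives are returned in the original input
    order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}")
    order = sorted(range(len(records)),
                   key=lambda i: (-len(records[i].seq), i))
    kept_idx: list[int] = []
    kept_sets: list[set[str]] = []
    for i in order:
        kset = _kmer_set(records[i].seq, k)
        redundant = False
        for other in kept_sets:
            small = kset if len(kset) <= len(other) else other
            big = other if small is kset else kset
            if small and len(small & big) / len(small) > identity_threshold:
                redundant = True
                break
        if not redundant:
            kept_idx.append(i)
            kept_sets.append(kset)
    kept = set(kept_idx)
    return [records[i] for i in range(len(records)) if i in kept]


def split_dataset(records: Sequence[SequenceRecord],
                  test_fraction: float = 0.2,
                  seed: int = 0) -> DatasetSplit:
    """Stratified train/test split of labeled records, deterministic by seed."""
    ids = [r.id for r in records]
    labels = [r.label for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("all records must be labeled before splitting")
    if len(set(labels)) < 2:
        raise ValueError("stratified split requires both classes present")
    train_ids, test_ids = train_test_split(
        ids, test_size=test_fraction, random_state=seed, stratify=labels)
    return DatasetSplit(train=tuple(train_ids), test=tuple(test_ids))
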