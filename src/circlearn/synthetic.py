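"""Synthetic labeled datasets with the statistical structure the pipeline
assumes, so every stage can be exercised without downloads.

Negatives are i.i.d. uniform nucleotide sequences.  Positives share the
same background but carry planted reverse-complement word pairs: words of
length ``word_k`` are copied from the actually generated left flank and
their reverse complements are written into random right-flank positions —
exactly the signal the RCM score measures.  Conservation tracks are
Gaussian noise clipped to [0, 1] around 0.3 for negatives and
0.3 + ``conservation_shift`` for positives, so the conservation block can
carry class signal too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import ConservationTrack
from .rcm import reverse_complement
from .seqio import SequenceRecord, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the seed is mandatory for reproducibility."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (300, 500)
    flank_L: int = 100
    planted_pairs: int = 8
    word_k: int = 3
    conservation_shift: float = 0.2
    conservation_base: float = 0.3
    conservation_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be >= 0")
        if self.length_range[0] < 2 * self.word_k:
            raise ValueError("minimum length must be >= 2 * word_k")
        if self.planted_pairs > 0 and self.flank_L < 2 * self.word_k:
            raise ValueError(
                f"flank_L={self.flank_L} too short to plant words of "
                f"length {self.word_k}")


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[SequenceRecord, ...]
    tracks: dict[str, ConservationTrack]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def _count_words(chars: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(chars) - k + 1):
        w = "".join(chars[i:i + k])
        counts[w] = counts.get(w, 0) + 1
    return counts


def _plant_rcm_pairs(seq: list[str], length: int, flank: int, n_pairs: int,
                     k: int, rng: np.random.Generator) -> None:
    """Write reverse complements of left-flank words into the right flank.

    Destinations are non-overlapping so plantings never erase each other.
    The source word is drawn from left positions whose word W still has
    fewer right-flank occurrences of revcomp(W) than left occurrences of
    W — i.e. positions where the planting creates a genuine new
    reverse-complement match rather than saturating an existing min().
    """
    # non-overlapping destination starts within the right flank
    starts = np.arange(length - flank, length - k + 1)
    rng.shuffle(starts)
    destinations = []
    for dst in starts:
        if len(destinations) == n_pairs:
            break
        if all(abs(dst - d) >= k for d in destinations):
            destinations.append(int(dst))
    for dst in destinations:
        left = seq[:flank]
        right = seq[length - flank:]
        left_counts = _count_words(left, k)
        right_counts = _count_words(right, k)
        positions = np.arange(flank - k + 1)
        rng.shuffle(positions)
        chosen = None
        for src in positions:
            word = "".join(left[src:src + k])
            rc = reverse_complement(word)
            if right_counts.get(rc, 0) < left_counts[word]:
                chosen = word
                break
        if chosen is None:  # every left word already fully matched
            chosen = "".join(left[int(positions[0]):int(positions[0]) + k])
        seq[dst:dst + k] = list(reverse_complement(chosen))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate records, conservation tracks and labels, deterministically."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    k, L = config.word_k, config.flank_L
    records: list[SequenceRecord] = []
    tracks: dict[str, ConservationTrack] = {}

    def make_track(rec_id: str, length: int, positive: bool) -> None:
        mean = config.conservation_base + (
            config.conservation_shift if positive else 0.0)
        scores = np.clip(rng.normal(mean, config.conservation_sd, length),
                         0.0, 1.0)
        tracks[rec_id] = ConservationTrack(scores=scores)

    for i in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        flank = min(L, length // 2)
        _plant_rcm_pairs(seq, length, flank, config.planted_pairs, k, rng)
        rec = SequenceRecord(id=f"pos{i}", seq="".join(seq), label=1,
                             source="synthetic")
        records.append(rec)
        make_track(rec.id, length, positive=True)

    for i in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        rec = SequenceRecord(id=f"neg{i}", seq="".join(_random_seq(rng, length)),
                             label=0, source="synthetic")
        records.append(rec)
        make_track(rec.id, length, positive=False)

    return SyntheticDataset(records=tuple(records), tracks=tracks)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit FASTA + label TSV + bedGraph-like track files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, outdir / "sequences.fasta")
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("id\tlabel\n")
        for rec in dataset.records:
            fh.write(f"{rec.id}\t{rec.label}\n")
    with open(outdir / "conservation.tsv", "w") as fh:
        for rec in dataset.records:
            scores = dataset.tracks[rec.id].scores
            # run-length compress equal adjacent scores into intervals
            start = 0
            for i in range(1, len(scores) + 1):
                if i == len(scores) or scores[i] != scores[start]:
                    fh.write(f"{rec.id}\t{start}\t{i}\t{scores[start]:.5f}\n")
                    start = i
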