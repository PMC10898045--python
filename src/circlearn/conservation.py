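"""Per-base evolutionary-conservation descriptor (15 features).

Conservation scores (e.g. PhastCons, which lives in [0, 1]) are supplied
per base of each transcript.  The descriptor summarizes them as:

* global mean and standard deviation over all bases (2 values);
* maximum, mean and median of the per-exon mean scores (3 values) — when
  no exon annotation is given the whole sequence counts as one exon;
* for each threshold t in {0.1, ..., 1.0}: the fraction of bases that lie
  in runs of at least ``min_run`` consecutive bases scoring above t,
  normalized by sequence length (10 values).

Total: 15 features, named ``con1``..``con15``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import SequenceRecord

THRESHOLDS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))

CONSERVATION_FEATURE_NAMES = [f"con{i + 1}" for i in range(15)]


@dataclass(frozen=True)
class ConservationTrack:
    """Dense per-base conservation scores, optionally with exon intervals.

    Exon intervals are half-open 0-based (start, end), sorted and
    non-overlapping, all within the sequence bounds.
    """

    scores: np.ndarray
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores",
                           np.asarray(self.scores, dtype=float))
        n = len(self.scores)
        if self.exons is not None:
            exons = tuple(sorted(tuple(e) for e in self.exons))
            prev_end = 0
            for start, end in exons:
                if not (0 <= start < end <= n):
                    raise ValueError(
                        f"exon ({start}, {end}) out of bounds for length {n}")
                if start < prev_end:
                    raise ValueError(f"exon ({start}, {end}) overlaps another")
                prev_end = end
            object.__setattr__(self, "exons", exons)


def read_track(path: str | Path, record: SequenceRecord) -> ConservationTrack:
    """Read per-base scores for one record from a bedGraph-like 4-column TSV.

    Lines are ``id<TAB>start<TAB>end<TAB>score`` with half-open 0-based
    intervals; only lines matching the record id are used.  Uncovered bases
    score 0.0.  Overlapping intervals or intervals beyond the sequence
    length are errors.
    """
    n = len(record.seq)
    scores = np.zeros(n, dtype=float)
    covered = np.zeros(n, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns (id, start, end, score)")
            if parts[0] != record.id:
                continue
            start, end, score = int(parts[1]), int(parts[2]), float(parts[3])
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"{path}:{lineno}: interval ({start}, {end}) outside "
                    f"sequence {record.id!r} of length {n}")
            if covered[start:end].any():
                raise ValueError(
                    f"{path}:{lineno}: interval ({start}, {end}) overlaps "
                    "a previous interval")
            scores[start:end] = score
            covered[start:end] = True
    return ConservationTrack(scores=scores)


def _run_exceedance(scores: np.ndarray, threshold: float,
                    min_run: int) -> float:
    """Fraction of bases in runs of >= min_run consecutive scores > threshold."""
    above = scores > threshold
    if not above.any():
        return 0.0
    # run-length encode
    boundaries = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [len(above)]])
    total = 0
    for s, e in zip(starts, ends):
        if above[s] and (e - s) >= min_run:
            total += e - s
    return total / len(scores)


def conservation_features(track: ConservationTrack,
                          min_run: int = 2) -> pd.Series:
    """Compute the 15-value conservation descriptor for one track."""
    scores = track.scores
    if scores.size == 0:
        raise ValueError("empty conservation score vector")
    exons = track.exons or ((0, len(scores)),)
    exon_means = np.array([scores[s:e].mean() for s, e in exons])
    values = [
        float(scores.mean()),
        float(scores.std()),
        float(exon_means.max()),
        float(exon_means.mean()),
        float(np.median(exon_means)),
    ]
    values.extend(_run_exceedance(scores, t, min_run) for t in THRESHOLDS)
    return pd.Series(values, index=CONSERVATION_FEATURE_NAMES)
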