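"""Reverse-complement-match (RCM) descriptors of flanking sequences.

Reverse-complementary word pairs between the two flanks of a back-splice
region can base-pair into a hairpin that brings splice sites together and
promotes circularization.  The descriptor counts, for every k-mer word W_i
in the left flank, occurrences of W_i on the left against occurrences of
its reverse complement W_R on the right, and scores the matched mass

    H(k, L0) = sum_i H_i,        H_i = min(N(W_i), N(W_R)),

where N(W_i) counts W_i in the left flank and N(W_R) counts W_R in the
right flank, both by overlapping sliding windows of stride 1.  The feature
block exposes the per-word values H_1..H_{4^k} (names ``rcm1``..) plus the
scalar total (``rcm_total``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord

_COMPLEMENT_DNA = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_COMPLEMENT_RNA = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    """Reverse a sequence, then complement it (A-T/U, C-G; N stays N).

    The output alphabet follows the input: an RNA sequence (containing U)
    complements A to U; otherwise DNA complements are used.
    """
    table = _COMPLEMENT_RNA if "U" in seq else _COMPLEMENT_DNA
    out = []
    for pos, base in enumerate(reversed(seq)):
        if base not in table:
            orig_pos = len(seq) - 1 - pos
            raise ValueError(
                f"invalid character {base!r} at position {orig_pos}")
        out.append(table[base])
    return "".join(out)


@dataclass(frozen=True)
class FlankPair:
    """Left and right flanking sequences of equal length L."""

    left: str
    right: str

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError(
                f"flanks must have equal length, got {len(self.left)} "
                f"and {len(self.right)}")

    @property
    def L(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class RcmProfile:
    """Per-word reverse-complement match counts and the total H score.

    Attributes
    ----------
    k : word length; D = 4**k is the word vocabulary size.
    L0 : flank length used; L1 = L0 - k + 1 sliding windows per flank.
    counts_left : occurrences N(W_i) of each word in the left flank.
    counts_right : occurrences N(W_R) of each word's reverse complement
        in the right flank.
    hi : per-word H_i = min(N(W_i), N(W_R)).
    """

    k: int
    L0: int
    counts_left: np.ndarray
    counts_right: np.ndarray
    hi: np.ndarray

    stride: int = 1

    @property
    def D(self) -> int:
        return 4 ** self.k

    @property
    def L1(self) -> int:
        return self.L0 - self.k + 1

    @property
    def h_total(self) -> int:
        return int(self.hi.sum())


def all_words(k: int) -> list[str]:
    """The 4^k DNA words of length k in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _word_counts(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts over the 4^k vocabulary; windows with N skipped."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    idx = 0
    valid = 0  # bases of the current window already encoded
    for base in seq:
        code = _BASE_INDEX.get(base)
        if code is None:
            idx, valid = 0, 0
            continue
        idx = ((idx << 2) | code) & (4 ** k - 1)
        valid = min(valid + 1, k)
        if valid == k:
            counts[idx] += 1
    return counts


def _revcomp_index_map(k: int) -> np.ndarray:
    """index of revcomp(word) for each word index, via bit arithmetic."""
    n = 4 ** k
    words = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    tmp = words.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))  # complement: A<->T, C<->G is 3-x
        tmp >>= 2
    return rc


def derive_flanks(record: SequenceRecord, L: int = 250,
                  flank_source: dict[str, FlankPair] | None = None) -> FlankPair:
    """Extract the two L-nt flanks of a transcript.

    Default "terminal" policy: left = first L bases, right = last L bases.
    Sequences shorter than 2L are split at the midpoint and each half is
    right-padded with N up to L.  If flank_source is given (the "external"
    policy), flanks are looked up by record id instead.
    """
    if flank_source is not None:
        if record.id not in flank_source:
            raise KeyError(f"no external flanks for record {record.id!r}")
        return flank_source[record.id]
    if L < 1:
        raise ValueError(f"flank length must be >= 1, got {L}")
    seq = record.seq
    if len(seq) >= 2 * L:
        return FlankPair(left=seq[:L], right=seq[-L:])
    mid = len(seq) // 2
    left = seq[:mid].ljust(L, "N")
    right = seq[mid:].ljust(L, "N")
    return FlankPair(left=left[:L], right=right[:L])


def rcm_score(flanks: FlankPair, k: int = 3) -> RcmProfile:
    """Count reverse-complement word matches between the two flanks."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > flanks.L:
        raise ValueError(f"k={k} exceeds flank length L={flanks.L}")
    counts_left = _word_counts(flanks.left, k)
    right_counts = _word_counts(flanks.right, k)
    rc = _revcomp_index_map(k)
    counts_right = right_counts[rc]  # N(W_R) indexed by W_i
    hi = np.minimum(counts_left, counts_right)
    return RcmProfile(k=k, L0=flanks.L, counts_left=counts_left,
                      counts_right=counts_right, hi=hi)


def rcm_feature_names(k: int = 3) -> list[str]:
    return [f"rcm{i + 1}" for i in range(4 ** k)] + ["rcm_total"]


def rcm_feature_vector(flanks: FlankPair, k: int = 3) -> pd.Series:
    """The "rcm" feature block: per-word H_i values plus the scalar total."""
    prof = rcm_score(flanks, k)
    values = np.concatenate([prof.hi, [prof.h_total]]).astype(float)
    return pd.Series(values, index=rcm_feature_names(k))


def sweep_kl(records: Sequence[SequenceRecord],
             k_values: Iterable[int] = (1, 2, 3, 4),
             L_values: Iterable[int] = (250, 500, 750, 1000, 1250, 1500, 1750),
             ) -> pd.DataFrame:
    """Class-wise mean/SD of the H score over a (k, L) parameter grid.

    Returns a tidy table with columns k, L, class, mean_H, sd_H, n — the
    data behind a flank-length / word-length optimization plot.
    """
    rows = []
    for k in k_values:
        for L in L_values:
            by_class: dict[object, list[int]] = {}
            for rec in records:
                h = rcm_score(derive_flanks(rec, L=L), k=k).h_total
                by_class.setdefault(rec.label, []).append(h)
            for cls, values in sorted(
                    by_class.items(), key=lambda kv: str(kv[0])):
                arr = np.asarray(values, dtype=float)
                rows.append({"k": k, "L": L, "class": cls,
                             "mean_H": float(arr.mean()),
                             "sd_H": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                             "n": len(arr)})
    return pd.DataFrame(rows)
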