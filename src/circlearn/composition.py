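"""Sequence-composition descriptors: k-mer frequencies, dinucleotide
auto-covariance (DAC) and pseudo k-nucleotide composition (PseKNC).

The concatenated block is named ``seq1``..``seqM`` with a fixed dimension
independent of sequence length: 4 + 16 + 64 k-mer frequencies (k = 1..3),
6 properties x lag_max auto-covariances, and 4 + lambda pseudo-composition
terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rcm import _word_counts, all_words

# Dinucleotide physicochemical indices (B-DNA step parameters): rise (Å),
# roll, shift (Å), slide (Å), tilt and twist (degrees), as tabulated in the
# standard dinucleotide property compilations used for autocorrelation
# descriptors of nucleic acids.
DINUC_PROPERTY_TABLE = pd.DataFrame(
    {
        "rise":  [3.16, 3.41, 3.63, 3.89, 3.23, 4.08, 3.60, 3.63, 3.47, 3.81,
                  4.08, 3.41, 3.21, 3.47, 3.23, 3.16],
        "roll":  [2.3, -2.0, 0.5, -8.1, 7.4, 1.0, 6.3, 0.5, 4.4, 3.7, 1.0,
                  -2.0, 1.9, 4.4, 7.4, 2.3],
        "shift": [-0.04, 0.12, 0.02, -0.04, 0.06, 0.05, 0.05, 0.02, 0.05,
                  0.05, 0.05, 0.12, 0.01, 0.05, 0.06, -0.04],
        "slide": [-0.18, -0.57, -0.22, -0.61, -0.05, -0.07, 0.44, -0.22,
                  -0.01, -0.13, -0.07, -0.57, 0.04, -0.01, -0.05, -0.18],
        "tilt":  [-0.5, -2.7, -0.1, -7.3, 0.9, -1.1, 3.3, -0.1, 1.3, 0.0,
                  -1.1, -2.7, 1.7, 1.3, 0.9, -0.5],
        "twist": [35.1, 31.5, 31.9, 29.3, 37.3, 32.9, 36.1, 31.9, 36.3,
                  33.6, 32.9, 31.5, 37.8, 36.3, 37.3, 35.1],
    },
    index=all_words(2),
)


def kmer_freqs(seq: str, k: int) -> np.ndarray:
    """Normalized overlapping k-mer frequencies over the 4^k vocabulary.

    Windows containing N are skipped and the denominator reduced
    accordingly, so frequencies still sum to 1 whenever at least one valid
    window exists.
    """
    seq = seq.upper().replace("U", "T")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    counts = _word_counts(seq, k)
    total = counts.sum()
    if total == 0:
        return np.zeros(4 ** k)
    return counts / total


def _dinuc_series(seq: str, prop: np.ndarray) -> np.ndarray:
    """Property value of the dinucleotide starting at each position."""
    idx_map = {"A": 0, "C": 1, "G": 2, "T": 3}
    values = []
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if a in idx_map and b in idx_map:
            values.append(prop[idx_map[a] * 4 + idx_map[b]])
    return np.asarray(values, dtype=float)


def dac(seq: str, properties: pd.DataFrame | None = None,
        lag_max: int = 2) -> pd.Series:
    """Dinucleotide auto-covariance for each property and lag 1..lag_max.

    For property u with per-position series P_u(i) and sequence mean
    mean_u, the value at lag d is the mean over i of
    (P_u(i) - mean_u)(P_u(i+d) - mean_u).
    """
    seq = seq.upper().replace("U", "T")
    if properties is None:
        properties = DINUC_PROPERTY_TABLE
    if len(seq) < lag_max + 2:
        raise ValueError(
            f"sequence length {len(seq)} too short for lag_max={lag_max}")
    out = {}
    for name in properties.columns:
        series = _dinuc_series(seq, properties[name].to_numpy())
        mean = series.mean()
        centered = series - mean
        for d in range(1, lag_max + 1):
            if len(series) <= d:
                raise ValueError("sequence too short for requested lag")
            out[f"{name}_lag{d}"] = float(
                np.mean(centered[:-d] * centered[d:]))
    return pd.Series(out)


def pseknc(seq: str, lam: int = 5, w: float = 0.1,
           properties: pd.DataFrame | None = None) -> np.ndarray:
    """Pseudo nucleotide composition: 4 mononucleotide terms + lam
    tier-correlation terms, jointly normalized to sum to 1.

    The tier-j correlation theta_j averages the squared property-profile
    distance between dinucleotides j apart (properties standardized
    column-wise).  Weight w balances composition against correlation; w = 0
    reduces to plain mononucleotide frequencies padded with zeros.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) <= lam + 1:
        raise ValueError(
            f"sequence length {len(seq)} must exceed lambda + 1 = {lam + 1}")
    if properties is None:
        properties = DINUC_PROPERTY_TABLE
    # standardized property matrix: 16 dinucleotides x P properties
    mat = properties.to_numpy()
    mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    idx_map = {"A": 0, "C": 1, "G": 2, "T": 3}
    dinuc_idx = [idx_map[seq[i]] * 4 + idx_map[seq[i + 1]]
                 for i in range(len(seq) - 1)
                 if seq[i] in idx_map and seq[i + 1] in idx_map]
    profile = mat[dinuc_idx]  # positions x properties
    thetas = []
    for j in range(1, lam + 1):
        if len(profile) <= j:
            raise ValueError("sequence too short for requested lambda")
        diff = profile[:-j] - profile[j:]
        thetas.append(float(np.mean(np.mean(diff ** 2, axis=1))))
    freqs = kmer_freqs(seq, 1)
    theta_sum = w * sum(thetas)
    denom = freqs.sum() + theta_sum
    head = freqs / denom
    tail = w * np.asarray(thetas) / denom
    return np.concatenate([head, tail])


def composition_feature_vector(seq: str, kmax: int = 3, lag_max: int = 2,
                               lam: int = 5, w: float = 0.1) -> pd.Series:
    """The full "seq" block: k-mers (k = 1..kmax) + DAC + PseKNC."""
    parts = [kmer_freqs(seq, k) for k in range(1, kmax + 1)]
    parts.append(dac(seq, lag_max=lag_max).to_numpy())
    parts.append(pseknc(seq, lam=lam, w=w))
    values = np.concatenate(parts)
    names = [f"seq{i + 1}" for i in range(len(values))]
    return pd.Series(values, index=names)


def composition_dim(kmax: int = 3, lag_max: int = 2, lam: int = 5) -> int:
    return sum(4 ** k for k in range(1, kmax + 1)) + 6 * lag_max + 4 + lam
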