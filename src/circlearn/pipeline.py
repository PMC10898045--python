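"""End-to-end featurization: assemble the four named feature blocks into
one matrix (samples x features).

Block naming follows the reporting convention used throughout the
package: ``rcm*`` (reverse-complement match), ``con*`` (conservation),
``graph*`` (structure-graph) and ``seq*`` (sequence composition).  The
conservation block is optional — when no tracks are supplied it is
omitted with a warning rather than failing, since per-base conservation
scores are the one input most users lack.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import composition_feature_vector
from .conservation import ConservationTrack, conservation_features
from .rcm import FlankPair, derive_flanks, rcm_feature_vector
from .seqio import SequenceRecord
from .structgraph import graph_feature_matrix, reduce_graph_features


def featurize(records: Sequence[SequenceRecord],
              tracks: Mapping[str, ConservationTrack] | None = None,
              flanks: Mapping[str, FlankPair] | None = None,
              k: int = 3, flank_L: int = 250,
              graph_top_n: int = 101, graph_n_bits: int = 15,
              graph_radius: int = 2, graph_distance: int = 4,
              include_graph: bool = True,
              seed: int = 0) -> pd.DataFrame:
    """Compute the full feature matrix for a set of labeled records.

    The hashed structure-graph block is reduced to its ``graph_top_n``
    most important columns by random-forest importance, which requires
    labels; for unlabeled records (prediction time) pass the kept column
    indices via featurize_like instead, or set include_graph=False.
    """
    index = [r.id for r in records]
    parts: list[pd.DataFrame] = []

    rcm_rows = [rcm_feature_vector(
        flanks[r.id] if flanks is not None else derive_flanks(r, L=flank_L),
        k=k) for r in records]
    parts.append(pd.DataFrame(rcm_rows, index=index))

    if tracks is not None:
        missing = [r.id for r in records if r.id not in tracks]
        if missing:
            raise KeyError(f"no conservation track for records {missing[:5]}")
        con_rows = [conservation_features(tracks[r.id]) for r in records]
        parts.append(pd.DataFrame(con_rows, index=index))
    else:
        warnings.warn("no conservation tracks supplied; 'con' block omitted",
                      stacklevel=2)

    if include_graph:
        labels = [r.label for r in records]
        if any(lab is None for lab in labels):
            raise ValueError(
                "graph-block reduction needs labeled records; "
                "set include_graph=False or label the records")
        full = graph_feature_matrix([r.seq for r in records],
                                    radius=graph_radius,
                                    distance=graph_distance,
                                    n_bits=graph_n_bits)
        reduced, kept = reduce_graph_features(full, labels,
                                              top_n=graph_top_n, seed=seed)
        reduced.index = pd.Index(index)
        reduced.attrs["kept_graph_columns"] = kept.tolist()
        parts.append(reduced)

    comp_rows = [composition_feature_vector(r.seq) for r in records]
    parts.append(pd.DataFrame(comp_rows, index=index))

    matrix = pd.concat(parts, axis=1)
    if include_graph:
        matrix.attrs["kept_graph_columns"] = reduced.attrs["kept_graph_columns"]
    matrix.attrs["rcm_k"] = k
    matrix.attrs["flank_L"] = flank_L
    matrix.attrs["graph_n_bits"] = graph_n_bits
    matrix.attrs["graph_radius"] = graph_radius
    matrix.attrs["graph_distance"] = graph_distance
    return matrix


def featurize_like(records: Sequence[SequenceRecord],
                   reference: pd.DataFrame,
                   tracks: Mapping[str, ConservationTrack] | None = None,
                   flanks: Mapping[str, FlankPair] | None = None,
                   ) -> pd.DataFrame:
    """Featurize new (possibly unlabeled) records with the same columns as
    a previously computed matrix (same rcm k, flank length, and kept
    hashed-graph columns)."""
    attrs = reference.attrs
    index = [r.id for r in records]
    parts: list[pd.DataFrame] = []
    k = attrs.get("rcm_k", 3)
    flank_L = attrs.get("flank_L", 250)
    rcm_rows = [rcm_feature_vector(
        flanks[r.id] if flanks is not None else derive_flanks(r, L=flank_L),
        k=k) for r in records]
    parts.append(pd.DataFrame(rcm_rows, index=index))
    if any(c.startswith("con") for c in reference.columns):
        if tracks is None:
            raise ValueError("reference matrix has a 'con' block; "
                             "conservation tracks are required")
        con_rows = [conservation_features(tracks[r.id]) for r in records]
        parts.append(pd.DataFrame(con_rows, index=index))
    kept = attrs.get("kept_graph_columns")
    if kept is not None:
        full = graph_feature_matrix([r.seq for r in records],
                                    radius=attrs.get("graph_radius", 2),
                                    distance=attrs.get("graph_distance", 4),
                                    n_bits=attrs.get("graph_n_bits", 15))
        reduced = pd.DataFrame(
            full[:, np.asarray(kept)],
            columns=[f"graph{i + 1}" for i in range(len(kept))], index=index)
        parts.append(reduced)
    comp_rows = [composition_feature_vector(r.seq) for r in records]
    parts.append(pd.DataFrame(comp_rows, index=index))
    matrix = pd.concat(parts, axis=1)
    return matrix[[c for c in reference.columns if c in matrix.columns]]
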