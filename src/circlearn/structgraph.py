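"""RNA secondary-structure graph features.

Each sequence is folded with a maximum-base-pair (Nussinov-style) dynamic
program (Watson-Crick A-U/T, C-G plus wobble G-U/T; minimum hairpin loop
of 3 unpaired bases), every base is annotated with its structural element
— stem (S), multiloop/"polyloop" (M), hairpin loop (H), internal loop (I),
bulge (B) or external region (E) — and the sequence plus structure is
encoded as a labeled graph: one node per nucleotide labeled
nucleotide+element (e.g. "CS" for a C inside a stem), backbone edges
between adjacent bases and base-pair edges between partners.

The graph is then decomposed into pairs of rooted neighborhood subgraphs
(a neighborhood-subgraph pairwise-distance kernel): for every radius
r <= ``radius`` and every pair of roots at shortest-path distance
d <= ``distance``, a canonical certificate of the two rooted subgraphs is
hashed into one of 2**n_bits bins, yielding an explicit sparse feature
vector.  A random forest ranks those features by impurity importance and
the top 101 are kept (names ``graph1``..``graph101``).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

MIN_HAIRPIN_LOOP = 3
_PAIRABLE = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
             ("G", "T"), ("T", "G")}

try:  # optional JIT for the O(L^3) fill
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco(args[0]) if args and callable(args[0]) else deco


@dataclass(frozen=True)
class SecondaryStructure:
    """Base-pairing (partner index per base, -1 = unpaired) and element labels."""

    pairs: tuple[int, ...]
    elements: tuple[str, ...] = ()

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


def structure_from_dot_bracket(db: str) -> SecondaryStructure:
    """Parse a (pseudoknot-free) dot-bracket string into a structure."""
    pairs = [-1] * len(db)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    struct = SecondaryStructure(pairs=tuple(pairs))
    return SecondaryStructure(pairs=struct.pairs,
                              elements=annotate_elements(struct))


@_njit(cache=True)
def _nussinov_fill(codes, pairable, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    outer = dp[k + 1, j] if k + 1 <= j else 0
                    cand = inner + 1 + outer
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_PAIR_MATRIX = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in _PAIRABLE:
    _PAIR_MATRIX[_CODE[_a], _CODE[_b]] = True


def fold(seq: str) -> SecondaryStructure:
    """Maximum-base-pair non-crossing fold with a minimum hairpin loop of 3.

    Ties are broken deterministically in the traceback: position i is
    paired with the smallest admissible partner whenever pairing attains
    the optimum.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    pairs = [-1] * n
    if n > MIN_HAIRPIN_LOOP + 1:
        codes = np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)
        dp = _nussinov_fill(codes, _PAIR_MATRIX, MIN_HAIRPIN_LOOP)
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or dp[i, j] == 0:
                continue
            paired = False
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if _PAIR_MATRIX[codes[i], codes[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    outer = dp[k + 1, j] if k + 1 <= j else 0
                    if inner + 1 + outer == dp[i, j]:
                        pairs[i], pairs[k] = k, i
                        if k - 1 >= i + 1:
                            stack.append((i + 1, k - 1))
                        if k + 1 <= j:
                            stack.append((k + 1, j))
                        paired = True
                        break
            if not paired:
                stack.append((i + 1, j))
    struct = SecondaryStructure(pairs=tuple(pairs))
    return SecondaryStructure(pairs=struct.pairs,
                              elements=annotate_elements(struct))


def annotate_elements(structure: SecondaryStructure) -> tuple[str, ...]:
    """Per-base structural element labels: S, M, H, I, B or E.

    Paired bases are stems (S).  An unpaired base is classified by the
    loop of its directly enclosing pair: hairpin (no nested pairs),
    bulge/internal loop (one nested helix, unpaired on one/both sides) or
    multiloop (several nested helices).  Bases outside every pair are
    external (E).
    """
    pairs = structure.pairs
    n = len(pairs)
    labels = ["E"] * n
    for i, j in enumerate(pairs):
        if j >= 0:
            labels[i] = "S"

    def classify_loop(p: int, q: int) -> str:
        # children = pairs directly nested inside (p, q)
        children = []
        unpaired = 0
        i = p + 1
        while i < q:
            if pairs[i] > i:
                children.append((i, pairs[i]))
                i = pairs[i] + 1
            else:
                unpaired += 1
                i += 1
        if not children:
            return "H"
        if len(children) >= 2:
            return "M"
        (cp, cq), = children
        left_gap = cp - p - 1
        right_gap = q - cq - 1
        if left_gap > 0 and right_gap > 0:
            return "I"
        return "B"

    # walk unpaired bases, find the directly enclosing pair via a stack
    enclosing: list[int] = []
    loop_label_cache: dict[tuple[int, int], str] = {}
    for i in range(n):
        j = pairs[i]
        if j > i:
            enclosing.append(i)
        elif 0 <= j < i:
            enclosing.pop()
        else:
            if enclosing:
                p = enclosing[-1]
                q = pairs[p]
                key = (p, q)
                if key not in loop_label_cache:
                    loop_label_cache[key] = classify_loop(p, q)
                labels[i] = loop_label_cache[key]
    return tuple(labels)


def encode_graph(seq: str, structure: SecondaryStructure) -> nx.Graph:
    """Sequence + structure as a labeled graph.

    Node labels concatenate nucleotide and element (e.g. "GS"); backbone
    edges connect adjacent bases, base-pair edges connect partners.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) != len(structure.pairs):
        raise ValueError("sequence and structure lengths differ")
    elements = structure.elements or annotate_elements(structure)
    g = nx.Graph()
    for i, (nuc, elem) in enumerate(zip(seq, elements)):
        g.add_node(i, nuc=nuc, element=elem, label=nuc + elem)
    for i in range(len(seq) - 1):
        g.add_edge(i, i + 1, kind="backbone")
    for i, j in enumerate(structure.pairs):
        if j > i:
            g.add_edge(i, j, kind="pair")
    return g


def _stable_hash(text: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


def _neighborhood_certificates(g: nx.Graph, radius: int) -> dict[int, list[str]]:
    """cert[v][r] = isomorphism-invariant certificate of the radius-r
    rooted neighborhood subgraph of v, for r = 0..radius."""
    adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
    node_label = {v: g.nodes[v]["label"] for v in g.nodes}
    certs: dict[int, list[str]] = {}
    for root in g.nodes:
        # BFS distances up to radius
        dist = {root: 0}
        frontier = [root]
        for d in range(1, radius + 1):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        per_r = []
        for r in range(radius + 1):
            members = [v for v, d in dist.items() if d <= r]
            member_set = set(members)
            # WL refinement rooted at `root`, r iterations
            lab = {v: f"{dist[v]}|{node_label[v]}" for v in members}
            for _ in range(r):
                lab = {
                    v: lab[v] + "(" + ",".join(
                        sorted(lab[w] for w in adj[v] if w in member_set)) + ")"
                    for v in members
                }
            cert = lab[root] + "#" + ",".join(sorted(lab.values()))
            per_r.append(hashlib.blake2b(cert.encode(),
                                         digest_size=8).hexdigest())
        certs[root] = per_r
    return certs


def nspdk_features(graph: nx.Graph, radius: int = 2, distance: int = 4,
                   n_bits: int = 15) -> np.ndarray:
    """Hashed subgraph-pair counts, dimension 2**n_bits.

    For every unordered root pair (u, v) at shortest-path distance
    d <= distance (including u = v at d = 0) and every radius r <= radius,
    the pair of rooted neighborhood certificates is hashed (seedless,
    platform-stable) into a bin.
    """
    dim = 2 ** n_bits
    vec = np.zeros(dim, dtype=np.float64)
    if graph.number_of_nodes() == 0:
        return vec
    certs = _neighborhood_certificates(graph, radius)
    adj = {v: list(graph.neighbors(v)) for v in graph.nodes}
    nodes = sorted(graph.nodes)
    for u in nodes:
        # BFS from u up to `distance`
        dist = {u: 0}
        frontier = [u]
        for d in range(1, distance + 1):
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in dist:
                        dist[b] = d
                        nxt.append(b)
            frontier = nxt
        for v, d in dist.items():
            if v < u:
                continue  # count each unordered pair once
            for r in range(radius + 1):
                ca, cb = sorted((certs[u][r], certs[v][r]))
                key = f"{r}|{d}|{ca}|{cb}"
                vec[_stable_hash(key) & (dim - 1)] += 1.0
    return vec


def graph_feature_matrix(seqs: Sequence[str], radius: int = 2,
                         distance: int = 4, n_bits: int = 15) -> np.ndarray:
    """Fold and featurize a batch of sequences (rows = sequences)."""
    rows = [nspdk_features(encode_graph(s, fold(s)), radius, distance, n_bits)
            for s in seqs]
    return np.vstack(rows)


def reduce_graph_features(matrix: np.ndarray, labels: Sequence[int],
                          top_n: int = 101, seed: int = 0,
                          n_estimators: int = 100,
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Keep the top_n hashed graph features by random-forest importance.

    Returns the reduced matrix with columns ``graph1``..``graph{top_n}``
    plus the kept column indices (in descending importance order).
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("graph feature reduction requires both classes")
    if top_n > matrix.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds available features ({matrix.shape[1]}); "
            "keeping all", stacklevel=2)
        top_n = matrix.shape[1]
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(matrix, labels)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    kept = order[:top_n]
    reduced = pd.DataFrame(
        matrix[:, kept], columns=[f"graph{i + 1}" for i in range(top_n)])
    return reduced, kept
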