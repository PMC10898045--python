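"""Secondary-structure folding and graph-kernel features.

Each sequence is folded by a maximum-base-pair dynamic program, bases are
labeled with structural elements (stem/hairpin/bulge/internal/multiloop/
external), and the labeled graph is hashed into a sparse feature vector
with a neighborhood-subgraph pairwise-distance kernel.
"""

from circlearn.structgraph import encode_graph, fold, nspdk_features

seq = "GGGCAAAAGCCCAUCCGGAUAU"
structure = fold(seq)
print("sequence:   ", seq)
print("dot-bracket:", structure.dot_bracket())
print("elements:   ", "".join(structure.elements))
print("base pairs: ", structure.n_pairs)

graph = encode_graph(seq, structure)
print(f"\ngraph: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges "
      "(backbone + base-pair)")
print("node labels (first 8):",
      [graph.nodes[i]["label"] for i in range(8)])

vec = nspdk_features(graph, radius=2, distance=4, n_bits=15)
print(f"\nhashed kernel vector: dimension {len(vec)}, "
      f"{int((vec > 0).sum())} occupied bins, total count {int(vec.sum())}")
print("Occupied bins index subgraph-pair shapes; two isomorphic graphs "
      "always occupy identical bins.")
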