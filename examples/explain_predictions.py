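"""Shapley-value interpretation of a trained classifier.

Kernel SHAP attributes each prediction to the input features; averaging
|SHAP| over samples ranks features, and the block prefix of each name
(rcm/con/graph/seq) shows which descriptor family drives the model.
"""

import warnings

import numpy as np

from circlearn.interpret import (block_tally, dependence_pair,
                                 shap_for_matrix, summary_rank, violin_data,
                                 top_features_per_block)
from circlearn.model import ModelConfig, train
from circlearn.pipeline import featurize
from circlearn.selection import select_features
from circlearn.synthetic import SyntheticConfig, generate

warnings.simplefilter("ignore")

ds = generate(SyntheticConfig(n_pos=40, n_neg=40, seed=4))
X = featurize(ds.records, tracks=ds.tracks, k=3, flank_L=100,
              graph_n_bits=12, seed=4)
ranked, Xsel = select_features(X, ds.labels, d=24, seed=4)
fitted = train(Xsel, ds.labels, config=ModelConfig.small(seed=4))

rng = np.random.default_rng(4)
background = Xsel.iloc[rng.choice(len(Xsel), 10, replace=False)]
explain = Xsel.iloc[rng.choice(len(Xsel), 20, replace=False)]
attr = shap_for_matrix(fitted, explain, background, n_samples=256, seed=4)

top = summary_rank(attr, top_n=10)
print("Top 10 features by mean |SHAP|:")
print(top.to_string(index=False))
print("\nBlock composition of the top 10:")
print(block_tally(top).to_string())

best = top["feature"].iloc[0]
dep = dependence_pair(attr, best)
print(f"\nDependence data for {best}: color feature = "
      f"{dep['color_feature'].iloc[0]} (the feature whose value best "
      "explains the spread of the attributions)")

violin = violin_data(Xsel, ds.labels, top_features_per_block(top, 1))
print("\nViolin-plot table (class 0 = positive, 1 = negative):")
print(violin.groupby(["feature", "class"])["value"].mean().round(3)
      .to_string())
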