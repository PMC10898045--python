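# Methods

This note documents the models and procedures implemented in
`circlearn`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Problem setting

The task is binary classification of transcripts: circRNA-producing
sequences (label 1) versus linear long non-coding RNAs (label 0), from
sequence-derived features only. Dataset preparation follows common
benchmark practice: transcripts shorter than 200 nt are removed (strict
`< 200`, so a 200-nt sequence is kept), near-duplicates are collapsed at
a 0.8 identity threshold, and evaluation uses stratified splits or
stratified ten-fold cross-validation.

Redundancy reduction is a greedy longest-first clustering on 5-mer
containment identity (shared 5-mers divided by the 5-mer count of the
shorter sequence). It deliberately avoids external binaries; it
reproduces the *role* of a 0.8-identity de-duplication pass, not the
cluster memberships of any particular clustering tool.

## Feature blocks

### Reverse-complement match (`rcm`, 4ᵏ + 1 values)

Two flanks of length L are taken per transcript; the default "terminal"
policy uses the first and last L bases (sequences shorter than 2L are
split at the midpoint and N-padded), and an "external" policy accepts
user-supplied flank FASTA keyed by record id. For every k-mer word Wᵢ,
N(Wᵢ) counts occurrences in the left flank and N(W_R) counts its
reverse complement in the right flank, both with overlapping windows of
stride 1; windows containing N count for no word. The score is
H = Σᵢ min(N(Wᵢ), N(W_R)). Matching is unidirectional
(left word, right reverse complement). The feature block is the per-word
vector H₁…H₄ᵏ plus the scalar total; per-word values are exposed because
individual matched words, not only the total, carry class information.
Defaults k = 3, L = 250; a `sweep_kl` helper tabulates class-wise mean H
over a (k, L) grid (k ∈ {1..4}, L ∈ {250, 500, …, 1750} by default) for
choosing these on new data.

Two useful identities, both under test: H is invariant to replacing
(left, right) with (revcomp(right), revcomp(left)), and appending a word
to the left flank together with its reverse complement to the right
flank never decreases H.

### Conservation (`con`, 15 values)

Input is one real score per base (PhastCons-style, in [0, 1]), read from
a bedGraph-like 4-column TSV; uncovered bases score 0. The descriptor
is: global mean and SD (2); maximum, mean and median of per-exon mean
scores (3; the whole sequence is one exon when no annotation is given);
and, for each threshold t ∈ {0.1, …, 1.0}, the fraction of bases lying
in runs of ≥ 2 consecutive bases scoring strictly above t (10). The
2 + 3 + 10 decomposition and the threshold grid are this package's
design; the grid covers the PhastCons range evenly. A single high base
is not a run by default (`min_run = 2`, configurable) — exceedance is
meant to capture sustained conserved stretches, not isolated spikes.

### Structure graph (`graph`, 101 values)

Folding is a Nussinov-style maximum-base-pair dynamic program with
Watson–Crick plus G·U wobble pairs and a minimum hairpin loop of 3;
traceback tie-breaks deterministically by pairing the smallest left
index first. This is a deliberate, self-contained substitute for
thermodynamic (MFE) folding: the downstream kernel needs a plausible,
reproducible secondary structure, not free-energy accuracy, and the
folder is verified exactly against exhaustive structure enumeration on
short sequences. Pseudoknots are out of scope.

Unpaired bases are classified by the loop of their directly enclosing
pair — hairpin (no nested helix), bulge/internal loop (one nested helix,
unpaired on one/both sides), multiloop (≥ 2 nested helices) — or
external. The labeled graph (node label = nucleotide + element, e.g.
"CS"; backbone and base-pair edges) is decomposed into pairs of rooted
neighborhood subgraphs: for radii r ≤ 2 and root distances d ≤ 4, a
root-distinguished Weisfeiler–Lehman certificate of each rooted
subgraph is computed, and the (r, d, certificate-pair) string is hashed
into 2¹⁵ bins with a seedless, platform-stable 64-bit hash (no
process-randomized hashing, so feature vectors are stable across runs
and machines). The certificate is isomorphism-invariant, which gives
the kernel its permutation invariance; as with any hashed kernel,
collisions merge bins but never create asymmetry between isomorphic
graphs. A random forest (100 trees, fixed seed) then ranks the bins by
impurity importance and the top 101 are kept as `graph1..graph101`.

### Composition (`seq`, 105 values)

k-mer frequencies for k = 1..3 (overlapping windows; N-containing
windows are skipped and the denominator reduced), dinucleotide
auto-covariance at lags 1–2 over six bundled B-DNA step parameters
(rise, roll, shift, slide, tilt, twist), and pseudo nucleotide
composition with λ = 5 tier-correlation terms and weight w = 0.1
(standard normalization: all 4 + λ terms sum to 1; w = 0 degenerates to
mononucleotide frequencies). The composition defaults (k ≤ 3, lag ≤ 2,
λ = 5, w = 0.1) are conventional small values chosen once; the block
dimension is fixed at 105 regardless of sequence length.

## Feature selection

Seven base rankers each produce a full descending-relevance ordering:
ANOVA F; MRMD (min-max-normalized |Pearson r| with the label plus
min-max-normalized mean Euclidean distance to the other features);
equal-frequency-binned mutual information (a light proxy for MIC — grid
search adds nothing for ordering at this scale); |coefficients| of an
L1 logistic fit; greedy MRMR (binned-MI relevance minus mean |Pearson|
redundancy); chi-square on min-max-scaled features; and RFE with a
linear model (one feature per round, batched above 200 features). Ties
break by column position, so orderings are deterministic.

The orderings are merged into a directed graph: for every ranking, the
feature at rank j+1 points at the feature at rank j ("worse endorses
better"), parallel edges accumulating weight. Weighted PageRank
(damping 0.85, uniform teleport, dangling mass spread uniformly,
L1 tolerance 1e-9) scores the nodes and features are selected in
descending score. When all rankings agree, this provably reproduces the
unanimous ordering (scores along a chain are strictly increasing toward
the best node) — a property under brute-force test. With heterogeneous
rankings the adjacent-pair graph is a deliberately local aggregation:
the unanimous-top feature is *usually* but not *necessarily*
PageRank-maximal, because endorsement mass can be diverted below the
top; strongly signalled features reliably land in the top handful
rather than exactly first. `d = "auto"` picks the selected size by
5-fold CV accuracy of a logistic probe over a geometric grid of sizes.

## Classifier

One convolutional branch per feature block, the block treated as a 1-D
sequence of feature positions: valid convolution (kernel 3), per-channel
batch normalization, ReLU, max-pool 2 (the pool window shrinks for
branches shorter than the pool, so every branch keeps ≥ 1 position;
blocks narrower than the kernel are zero-padded). Branch outputs are
concatenated along the position axis and read by a bidirectional LSTM;
the final forward and backward hidden states feed dense 128 → 64 (ReLU,
inverted dropout 0.5) and a 2-way softmax. Optimization is Adam at
learning rate 0.001, batch size 64, up to 200 epochs with early
stopping on validation accuracy (patience 10), restoring the best
weights; accuracy ties are broken toward lower validation loss so that
among equally accurate epochs the better-calibrated one is kept. The
whole network runs in seeded, single-threaded numpy with hand-written
backpropagation, pinned by numerical-gradient tests — fixed seeds give
bit-identical histories.

`ModelConfig.small()` (8 filters, 8 LSTM units, dense 32/16, dropout
0.3, lr 3e-3, ≤ 100 epochs with a 40-epoch floor before early stopping
may trigger) is the preset used by the cross-validation runs, examples
and the acceptance script; at a few hundred samples the full-width
architecture adds cost but no measurable accuracy, and the epoch floor
prevents premature stops on tiny validation splits.

Metrics: SE = TP/(TP+FN), SP = TN/(TN+FP), ACC, MCC by the determinant
formula with 0 returned when any confusion-matrix marginal is zero, and
AUC as the Mann–Whitney rank statistic of the positive-class score
(mid-ranks on ties). Cross-validation is stratified; feature selection
is re-fitted inside each training fold, so no test information reaches
the selected feature set. The hashed-graph-block reduction to 101
columns is part of featurization (it precedes and is separate from the
seven-ranker selection stage).

## Shapley-value interpretation

Attributions target the positive-class probability. The estimator is
the kernel-weighted coalition regression form of Shapley values: the
model is evaluated on hybrids of the explained row and background rows,
and a weighted least squares fit under the additivity constraint
(base value + Σφ = model output, enforced exactly by eliminating one
coefficient) recovers φ. When 2^M − 2 ≤ n_samples the coalition space is
enumerated with exact Shapley kernel weights — the estimate is then the
exact Shapley value of the background-replacement value function, and is
verified against closed-form linear attributions and brute-force
permutation enumeration. Otherwise coalitions are drawn (antithetic
pairs, sizes following the kernel distribution) with a fixed seed.
Summary ranking is mean |φ| per feature with block-prefix tallies;
dependence pairs pick the coloring feature whose values correlate most
with the target's attributions within value bins of the target (the
single-feature case degenerates to the feature itself); violin tables
use the figure convention class 0 = positive, 1 = negative.

## Synthetic data

The generator emulates exactly the signals the pipeline measures.
Negatives are i.i.d. uniform sequences. Positives plant
reverse-complement word pairs: a word is copied from the generated left
flank and its reverse complement written into the right flank, with
non-overlapping destinations, and the source word drawn from positions
where the planting creates a new match (right-flank count of the
reverse complement still below the left-flank count) — without that
eligibility rule most plantings vanish into the min() saturation of
background k-mer counts. Conservation tracks are clipped Gaussians
(SD 0.1) around 0.3 for negatives and 0.3 + shift for positives.
Defaults: 200 + 200 sequences of 300–500 nt, flanks of 100 nt, 8 planted
pairs of length 3, conservation shift 0.2 — at these settings the
class gap in mean H is ≈ 6.5 and the dataset is separable by design.

What the generator does **not** emulate: real base composition and
length distributions, genuine back-splice junctions or intronic flanks,
phylogenetically structured conservation, or correlated noise between
blocks. Passing tests on this data demonstrates that the pipeline
recovers the signals it claims to measure when present; it says nothing
about accuracy on real transcript catalogs.

## Problem sizes and numerical conventions

Cross-validation and acceptance runs use 400 samples, ten folds,
selection to d = 64 and the small network preset — sizes chosen so a
full from-scratch run completes in minutes on one CPU while every stage
(including fold-local selection and SHAP) still executes at realistic
dimensionality. Degenerate inputs are errors, not silent defaults:
empty score vectors, single-class labels for stratified operations,
k exceeding the flank length, coalition backgrounds of mismatched
width. Tolerances: PageRank scores sum to 1 within 1e-9 and match power
iteration within 1e-8; k-mer frequencies sum to 1 within 1e-9;
enumerated SHAP matches brute force to ~1e-8; sampled SHAP satisfies
additivity exactly by construction.

## Known limitations

* The folder maximizes pair count, not free energy; structures are
  plausible, not thermodynamically optimal.
* Hashed graph features are collision-prone by construction; the
  dimension (2¹⁵) trades collision rate against memory.
* The adjacent-pair PageRank aggregation is order-local (see above);
  consumers needing a guarantee that a unanimous top feature ranks
  first should inspect the per-ranker report.
* Kernel SHAP with sampled coalitions inherits Monte-Carlo noise; the
  seed makes it reproducible, not exact.
* The conservation descriptor assumes scores in [0, 1]; phyloP-style
  unbounded scores should be rescaled before use.
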