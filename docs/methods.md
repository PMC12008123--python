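# Methods

## Problem setting and data model

`supenh` is a binary sequence classifier: class 1 is the super-enhancer
(SE), class 0 the typical enhancer (TE). Inputs are uppercase A/C/G/T/N
sequences; real SE/TE sets derived from enhancer databases span roughly
0–3000 bp, and the package targets that regime. Records shorter than 9 bp
are rejected at validation (each of the three segments must admit at least
one trinucleotide window); they are reported and skipped at dataset level
rather than silently zero-filled.

## Tri-segmentation

Every encoder operates on the three contiguous thirds of a sequence
(upstream, midstream, downstream). For length L the base segment length is
`floor(L/3)`; a remainder of 1 or 2 is assigned one extra base to the
earliest segments (upstream first). This rule is deterministic, preserves
order, keeps segment lengths within 1 of each other, and the concatenation
always reproduces the input exactly. All windows are 0-based, half-open.

Ambiguous bases (N) are retained in sequences; any k-mer window containing
an N is simply skipped by every encoder — it contributes neither to
embedding sums nor to frequency numerators or denominators. No imputation
is attempted.

## Deep features: tri-segment k-mer embedding sums

Given an embedding matrix `w` mapping each k-mer to a `dim`-vector
(default `dim = 64`), a segment of length L yields exactly `L − k + 1`
stride-1 windows whose vectors are **summed** (not averaged) into the
segment vector. The per-record feature is the concatenation over segments
and over k ∈ {4, 5, 6}: 3 segments × 3 k-values × 64 dims = 576 features,
named `k{K}_seg{J}_d{D}`. Consequences of the sum convention: features
scale with segment length (no length normalization is applied), and the
representation depends only on the multiset of windows, not their order.

Embedding matrices are pluggable inputs in word2vec text format and must
cover all 4^k k-mers; k-mers absent from a loaded file fall back to the
zero vector with a warning. Two sources ship with the package:

- `make_embedding_fixture`: seeded standard-normal matrices. These are
  synthetic stand-ins with the right shape and determinism but no genomic
  co-occurrence structure; they act as a fixed random projection of k-mer
  composition, which is sufficient for the planted-composition benchmarks.
- `train_embedding`: a compact numpy skip-gram with negative sampling
  (window 4, 5 negatives, unigram^0.75 noise, seeded mini-batch SGD on one
  thread, hence bitwise reproducible). It is intended for small corpora;
  genome-scale embedding training is out of scope.

## Shallow features: composition and PseEIIP

The per-segment trinucleotide distribution uses stride-1 windows
normalized by the number of *valid* windows, so each 64-entry block sums
to 1 whenever at least one valid window exists (all-N segments give a
zero block with a warning). Blocks are concatenated upstream → midstream →
downstream (192 features, `comp_{seg}_{XYZ}`).

PseEIIP multiplies each trinucleotide frequency by the trinucleotide's
electron–ion interaction pseudopotential. The mononucleotide constants are
A 0.1260, T 0.1335, G 0.0806, C 0.1340. The trinucleotide value is the
**sum** of the three constituents by default — the convention of the
PseEIIP literature — with a `mean` switch (a global ×1/3 rescaling,
irrelevant to scale-invariant classifiers) retained because descriptions
of the encoding vary on this point. By construction the PseEIIP block
equals the composition block times the tiled tri-EIIP vector, exactly;
the test suite asserts this identity rather than tolerating it.

Fusing composition and PseEIIP gives the 384-d shallow vector.

## F-score selection

For feature j with class means x̄⁺, x̄⁻, overall mean x̄ and unbiased
within-class variances s²⁺, s²⁻:

    F(j) = [(x̄⁺ − x̄)² + (x̄⁻ − x̄)²] / [s²⁺ + s²⁻]

The denominator is the **sum** of the two within-class variances; a
difference there can be zero or negative, which would contradict the
defining property that larger F means more discriminative, so the sum is
the only self-consistent reading. Features with zero pooled within-class
variance but separated means score +inf and sort first; globally constant
features score 0. Ties break by feature index (stable sort), making the
ranking fully deterministic. The score is invariant to rescaling a feature
(both numerator and denominator scale by c²).

The stepwise sweep re-trains a baseline classifier (standard-scaled RBF
SVM) on the top n = 10, 20, … features using a single stratified 80/20
split of the training data, and keeps the accuracy argmax (earliest n on
ties; the final n always covers the full feature count). Selection is
fitted on training data only and frozen before any test data is touched,
and it applies **only** to the shallow features — the deep embedding
features bypass selection and go to the deep model whole.

## Deep classifier

The 576-d vector is viewed as 9 tokens of width 64, one per (k, segment)
block in encoding order, giving attention/convolution/recurrence a
sequence axis. Architecture: multi-head self-attention (4 heads, residual
connection) → two 1-D convolution blocks (64 filters, kernels 3 and 5,
ReLU, same padding) → max-pool 2 → GRU (64 units, last hidden state) →
dropout 0.3 → dense 64 (ReLU) → dense 1 → sigmoid. Head count must divide
the token width, enforced at construction.

Training: Adam (lr 1e-3, batch 64, ≤ 40 epochs), binary cross-entropy,
early stopping on validation loss with patience 6 and restoration of the
best parameters; inputs are standardized per column with training-split
statistics. A non-finite loss aborts with a diagnostic; fewer than 50
training samples logs an overfitting warning. The network is a float64
numpy implementation on a small reverse-mode autodiff core
(`supenh/_autodiff.py`) whose gradients are verified against central
differences in the test suite; single-threaded execution makes training
reproducible under a fixed seed. Layer sizes are declared defaults chosen
as modest capacity for 576-d inputs and datasets of hundreds-to-thousands
of sequences; nothing in the architecture is tuned per dataset.

## Shallow bank and ensemble

Six classical algorithms — SVM (standard-scaled, Platt-calibrated),
LightGBM, XGBoost, gradient-boosted trees, random forest, extremely
randomized trees — are fitted with library-default hyperparameters and
pinned seeds on one thread. Members are ranked by validation accuracy with
AUROC and then algorithm name as deterministic tie-breaks.

The ensemble is unweighted soft voting over class-1 probabilities.
Probabilities are validated to [0, 1]; the vote is bounded by the member
minimum/maximum and invariant to member order. Hard labels use threshold
0.5 with exact ties going to the positive class (a declared convention).

Member sets are chosen by an incremental search that mirrors how such
ensembles are assembled in practice: starting from the deep model, the
top-ranked shallow members are added one at a time (deep+1, deep+2, …, up
to four by default), each candidate set is scored by soft vote on the
validation split, and the set with the maximum accuracy wins, smallest set
on ties. An exhaustive-subset mode exists but is off by default. No
weighted voting, stacking, or meta-learning.

## Evaluation

ACC, Precision, Recall and F1 come from the 2×2 confusion table with
class 1 positive; undefined precision/recall denominators are reported as
a flagged 0 with a warning (never NaN), keeping repeated-run aggregation
total. AUROC is the trapezoidal area (equal to the tie-averaged
Mann–Whitney rank statistic — the tests assert the equivalence against an
independent rank-statistic oracle); AUPR uses step interpolation (average
precision). `repeated_evaluation` re-runs a seeded split/train/score cycle
with seeds `base_seed + r` (default 5 repeats, configurable) and reports
per-run values, means and dispersions; failed runs yield a partial report
with a failure log.

## Synthetic benchmark: what it does and does not emulate

The generator draws i.i.d. uniform A/C/G/T background (so every 3-mer has
null expectation 1/64), lengths uniform on [200, 3000] bp by default —
within the 0–3000 bp regime of real SE/TE sets, excluding only the rare
sub-200 bp tail — and plants signal by emitting, at each step inside a
target segment of a positive sequence, a whole enriched 3-mer with
probability `delta` instead of one background base (tail truncated to the
exact segment length). Defaults: 400 sequences per class, AAA and GGG
enriched at delta 0.3 in the midstream segment only. This yields a known,
tunable, segment-localized composition difference — the test bed for rank
recovery, for chance-level null controls (delta 0), and for the
segment-entropy diagnostic.

It does **not** emulate real genomic context: no ChIP-seq signal, no
GC-content or repeat structure, no motif grammar, no co-occurrence
statistics for embeddings to learn. Passing the recovery tests therefore
demonstrates that the pipeline's machinery is correct and sensitive to
segment-localized composition signal at realistic lengths and sample
sizes — not that any particular accuracy will be attained on real SE/TE
data.

## Entropy diagnostic

For any region (each segment or the whole sequence) the trinucleotide
Shannon entropy is `−Σ f log₂ f` over the 64-outcome distribution
(0 ≤ H ≤ 6 bits; zero frequencies contribute nothing; log base 2 is a
declared choice). The tidy per-record table (record, region, entropy,
label) supports box-plot comparison of SE vs TE information content per
region; on planted data the positive/negative entropy gap appears in the
planted segment and nowhere else.

## Problem sizes used in checks

The packaged acceptance checks and `scripts/acceptance.py` run the
generator at its default study conditions (400/400 planted, 600/600 null,
80/20 splits, three seeds where repetition is called for). These sizes
give stable statistics — e.g. the null-AUROC sampling s.d. on a
240-sample test set is ≈ 0.037, well inside the [0.4, 0.6] chance band —
while keeping a full from-scratch run to a few minutes on one CPU.

## Known limitations

- The embedding fixtures carry no genomic semantics; results with them
  measure composition signal through a random projection, not learned
  k-mer context. For real use, supply matrices trained on genome corpora.
- Sum aggregation makes deep features length-sensitive; the deep model's
  input standardization absorbs most of this, but strongly length-skewed
  classes could leak length as a feature.
- The stepwise selector evaluates one nested chain, not all subsets, and
  its baseline SVM choice influences `chosen_dim` on weak-signal data.
- The deep network is a compact numpy implementation: fine for
  hundreds-to-thousands of 576-d inputs, not for genome-scale training.
- No class-imbalance handling (resampling/SMOTE) is included anywhere, by
  design; supply balanced or near-balanced training sets.
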