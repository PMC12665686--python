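# Methods

## The model

`screformer` implements a two-stage, BERT-style classifier for first-tier
cell-type annotation from scRNA-seq expression matrices. A cell is
represented as a fixed-order token sequence over the gene vocabulary — one
token per gene, carrying the gene's discretized expression level — and
encoded by a Reformer: a transformer whose attention is restricted by
locality-sensitive hashing (LSH) and whose residual connections are
reversible. Stage one pre-trains the encoder with a masked-expression
objective on unlabeled cells; stage two fine-tunes the full network with a
convolutional classification head on labeled cells.

### Input representation

Each gene position is embedded as the sum of three d_model-dimensional
terms:

- a **gene-identity embedding**, optionally initialized from a
  Gene2vec-style table (functionally related genes start close together;
  the table also acts as the vocabulary filter: genes with no nonzero
  expression or without an embedding are dropped before tokenization);
- a learned **expression-bin embedding**. Expression values are discretized
  into B bins (default B = 7): bin 0 is reserved for exactly-zero
  expression and the nonzero mass is split by empirical quantiles of the
  log1p-transformed nonzero training values (global edges by default,
  per-gene edges behind a switch). Edges are fit on training cells only and
  frozen with the model;
- the standard **sinusoidal positional encoding**.

Following the original transformer convention, the learned embeddings are
scaled by sqrt(d_model) before the positional term is added; without this
the fixed sinusoids dominate the summed representation and the token
content carries a vanishing share of the variance. The bin table has one
extra row, the reserved MASK token used in pre-training.

### LSH attention

Attention uses the shared-QK regime of the Reformer: keys are the
row-normalized queries, so the bucket of a query and of the corresponding
key coincide by construction. Each hash round projects the query onto a
seeded rotation matrix R (d_k x n_buckets/2) and assigns
bucket = argmax[xR, -xR]; rotations are stacked QR-orthonormalized blocks
rather than raw Gaussians because unequal column norms skew bucket
occupancy. Position j belongs to P_i when i and j share a bucket in at
least one of n_hash_rounds rounds (default 4), and row i softmaxes the
scaled scores over P_i only. A position always belongs to its own P_i; an
`exclude_self` flag removes the diagonal except for singleton buckets
(default off, so the single-bucket limit is exactly full attention).

At the sequence lengths this package targets (hundreds to a few thousand
genes), P_i is realised as a dense boolean mask over the score matrix —
exact restricted-softmax semantics, trivially verifiable against a
brute-force oracle. The sorted-chunk kernel that gives the original
Reformer its O(N log N) complexity on 10^4-10^5-token sequences is
intentionally not replicated; it approximates the same P_i and would add
substantial machinery without changing desk-scale results. Hash rotations
are drawn once per layer at construction and kept fixed, making evaluation
deterministic for a given seed.

### Reversible residual stack

Each of the n_layers blocks couples an attention sublayer F and a
feed-forward sublayer G (both pre-norm) as y1 = x1 + F(x2),
y2 = x2 + G(y1); the two half-states start as two copies of the embedded
input and the stack output is their mean, followed by the final layer norm
customary for pre-norm transformers. Because the coupling is invertible,
the backward pass can recompute every block's inputs from its outputs
instead of storing activations; both backward routes (stored caches and
recompute-on-backward) are implemented and agree to float tolerance, which
is how the constant-memory property is asserted.

All layers are NumPy with hand-written reverse-mode gradients (the
environment provides no autodiff framework); every layer's backward pass is
validated against central finite differences in the test suite.

### Pre-training (masked expression)

Per cell and epoch, each expressed (nonzero-bin) position is independently
selected with probability mask_prob = 0.15; a selected position carries the
MASK token with probability replace_prob = 0.9 and keeps its original bin
otherwise. Zero-expression positions are never masked. A linear head maps
the encoder feature at each masked position to B bin logits, trained with
the summed cross-entropy L = -sum_{i,j} log p_{i,j}[y_{i,j}]. The BERT
80/10/10 scheme's random-token branch is deliberately not used — only the
mask/keep split is specified by the protocol. Masks are resampled every
epoch. 10% of the pre-training cells are held out for monitoring; training
stops when the monitored loss has not improved by >= 1e-4 for 5 consecutive
epochs, and the best-monitored parameters are returned.

### Fine-tuning

A kernel-size-1 one-dimensional convolution (a shared projection applied to
every gene's feature vector, ReLU) feeds a pooling step over genes and a
three-layer perceptron producing C class logits. Pooling defaults to the
concatenation of mean and max over genes: the max path gives sharp credit
assignment to "some marker gene responds" detectors, which on
planted-marker data trains substantially faster than mean-only pooling
(mean-only is available as `pooling="mean"`). Dropout (default 0.1) applies
inside the head only. The loss is the summed cross-entropy
-sum_i log q_i[z_i]; all weights, embeddings through encoder to head, are
updated. Early stopping tracks validation accuracy with patience 1 by
default and always returns the best recorded checkpoint. Prediction breaks
argmax ties toward the lower class index.

Both stages use AdamW with a linear schedule and 10% warm-up. Library
defaults (d_model 200, 6 layers, 10 heads, 64 buckets, fine-tuning batch 6
with 60-step gradient accumulation, lr 1e-4, at most 3 epochs, seed 2022)
assume a labeled dataset of hundreds of thousands of cells; on the desk-scale fixtures used by the tests they give on the
order of one optimizer step per epoch, so the tests run small-model
configurations (d_model 32, 2 layers, 2 heads, 8 buckets, batch 32, no
gradient accumulation, lr 1e-3 to 1e-2, 10-25 epochs) chosen once as
sensible small-data training settings.

### Interpretation (Shapley attribution)

Attributions explain the pre-softmax logit of a chosen class (logits are
stable under class-count changes, unlike probabilities; the protocol does
not specify which). A "feature" is a gene's bin token, and feature removal
substitutes the token of a background cell, respecting the discreteness of
the representation. The estimator is model-agnostic permutation sampling:
per draw it samples a background cell and a random gene ordering, walks the
ordering switching tokens from background to explained values, and credits
each gene with its marginal change in model output. This converges to the
Shapley value; additivity (sum of attributions = f(x) - E_bg[f]) holds
within Monte-Carlo error. An exact enumerator over all 2^L coalitions
(feasible to L ~ 12) serves as the independent oracle in the tests.
Defaults — 500 background cells, 1000 explained cells of the target type,
ranking by mean |attribution| — are sized for real datasets and scaled
down on fixtures.

### Metrics

Confusion matrix (rows true, columns predicted), accuracy = trace/total,
macro-F1 (unweighted mean of per-class F1; a class with precision + recall
= 0 contributes 0, with a warning when it had neither members nor
predictions), and per-class one-vs-rest AUC computed as the tie-aware rank
statistic (ties count 1/2), equivalent to the ROC integral and exact under
ties; ROC curve points are exported for plotting. AUC for a class absent
from the truth is reported as NaN with a warning.

## Synthetic data

The generator emulates a 10x-style UMI count matrix with planted cell-type
structure. Gene baselines are log-normal around `base_mean` (sigma 0.5);
counts are gamma-Poisson (negative binomial, variance mu + mu^2/dispersion);
each of `n_types` types elevates its own disjoint module of
`markers_per_type` marker genes by `fold_change`; independent dropout zeroes
entries with probability `dropout_rate`. Labels form a 4-level hierarchy
(level 1 = type; deeper levels are generated sub-labels, with some branches
stopping early so the downward propagation rule is exercised). The
embedding table gives each marker module a shared latent direction with
expected within-module cosine `within_sim` (default 0.8), orthogonal across
modules; non-markers are isotropic.

Defaults (2000 cells x 300 genes, 5 types x 10 markers, fold change 6,
base mean 1, dispersion 2, dropout 0.3) plant a strong but noisy signal: a
nearest-centroid classifier on the true markers exceeds 90% accuracy, so
end-to-end failures indict the model rather than the data. What the
generator does *not* emulate: batch effects, doublets, ambient
contamination, library-size variation, realistic class imbalance, and the
gene-gene correlation structure of real regulatory networks beyond the
planted modules. Passing end-to-end tests therefore demonstrates that the
architecture and training loop can recover strong modular signal at small
scale — not that the model matches the large-scale accuracy achievable on
real tissue after corpus-scale pre-training.

Test and acceptance runs use a reduced instance of the same generative
conditions (600 cells x 120 genes) so the whole suite fits in minutes on
one CPU; the generator's own defaults are unchanged. The ablation check
(full model vs random embedding initialization vs no pre-training) runs in
the regime where the two-stage paradigm earns its keep: the encoder is
pre-trained on every cell without labels and fine-tuned briefly on a small
labeled subset (30 cells per type): pre-training on a large unlabeled
corpus is meant to carry the largest share of the performance precisely
when labels are scarce. With abundant labels and training to convergence the
supervised stage can relearn gene identity directly on a small vocabulary
and the ablation differences wash out — an expected scale effect, not a
property of the method.

## Numerical choices and edge cases

- Quantile bin edges may tie on discrete counts; tied edges collapse bins
  (monotonicity is preserved) and the top bin always contains the training
  maximum. An all-zero matrix cannot be binned (error); an all-zero cell
  tokenizes to all bin-0 and yields an empty mask set (warning).
- Probabilities at a cross-entropy target are clamped at 1e-12 with a
  warning.
- Masked attention scores use -1e30 rather than -inf so softmax stays
  finite; every row has at least one admissible key (itself).
- The zero vector hashes to bucket 0 by the argmax convention.
- Split allocation uses largest-remainder rounding per stratum, so realized
  counts are within one cell of the requested ratios for every class.
- Seeds: every estimator takes one integer seed; internal streams
  (initialization, splits, masking, batch order, hash rotations) are spawned
  from it, so a run is reproducible from config + seed alone.

## Known limitations

- Dense-mask LSH attention is O(L^2) memory; genuinely long vocabularies
  (>10^4 genes) would need the chunked kernel this package omits.
- The NumPy training loop is single-threaded BLAS-bound; it is sized for
  hundreds of cells and tens of thousands of parameters, not for atlases.
- Pre-training on a few hundred synthetic cells cannot reproduce the
  qualitative gains reported for 15M-cell corpora; the pre-training tests
  check that the objective is learnable (held-out loss beats the uniform
  baseline), not that transfer beats supervised training at this scale.
- Only level-1 labels are classified; deeper hierarchy levels are stored
  and propagated but not predicted.
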