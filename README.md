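# screformer

Reformer-BERT style cell-type classification for single-cell RNA-seq.

## The problem

Annotating the major cell categories (first-tier cell types) in an
scRNA-seq experiment from the full cell × gene count matrix is usually done
either by clustering + marker inspection or by supervised classifiers that
first throw away most of the gene space (highly-variable-gene selection,
PCA). `screformer` implements the alternative: a transformer classifier
that keeps every characterized gene as an input token, kept tractable by a
Reformer encoder — locality-sensitive-hashing (LSH) attention restricts
each gene's attention to genes hashed into the same bucket, and reversible
residual layers remove the need to store activations during
backpropagation. The model is trained in the BERT two-stage fashion:

1. **Masked-expression pre-training** (self-supervised): mask 15% of a
   cell's expressed genes (90% of them replaced by a MASK token) and
   reconstruct their expression bin from context, minimizing
   L = -Σᵢ Σⱼ log p_{i,j}[y_{i,j}].
2. **Supervised fine-tuning**: per-gene features → kernel-size-1 conv →
   pooling over genes → three-layer perceptron → C class probabilities,
   minimizing L = -Σᵢ log q_i[z_i], with early stopping on validation
   accuracy.

A cell enters the model as a fixed-order token sequence: each gene
contributes gene-identity embedding (optionally initialized from
Gene2vec-style vectors, which double as the vocabulary filter) + a learned
embedding of its expression **bin** (B = 7 quantile bins of log1p
expression, bin 0 reserved for zeros) + sinusoidal positional encoding.
Evaluation covers confusion matrix, accuracy, macro-F1 and per-class
one-vs-rest AUC; interpretation uses Shapley-value attribution of a class
logit over gene tokens (permutation sampling, with an exact enumerator for
verification). A synthetic-data module generates negative-binomial count
matrices with planted marker modules, a 4-level label hierarchy and a
matching embedding table, so everything is testable offline.

The whole network is NumPy with hand-written reverse-mode gradients —
validated against finite differences — so the package has no deep-learning
framework dependency.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from screformer import (SyntheticSpec, generate, ExpressionTokenizer,
                        MaskedExpressionPretrainer, ReformerCellClassifier, evaluate)

spec = SyntheticSpec(n_cells=600, n_genes=120, n_types=5, markers_per_type=10,
                     fold_change=6.0, dropout_rate=0.3, d_embed=32, seed=7)
ds = generate(spec)                                   # counts + labels + embeddings
tok = ExpressionTokenizer(n_bins=7, vocab=ds.embeddings).fit(ds.matrix)
X, y = tok.transform(ds.matrix), np.asarray(ds.labels.level1)
Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.2, stratify=y, random_state=0)

pre = MaskedExpressionPretrainer(d_model=32, n_layers=2, n_heads=2, n_buckets=8,
                                 n_hash_rounds=2, lr=1e-3, weight_decay=0.0,
                                 batch_size=32, max_epochs=20, seed=2022,
                                 gene_embeddings=ds.embeddings.lookup(tok.gene_ids_))
pre.fit(Xtr)
print(f"held-out reconstruction loss {pre.best_holdout_loss_:.3f} (uniform ln 7 = {np.log(7):.3f})")

clf = ReformerCellClassifier(d_model=32, n_layers=2, n_heads=2, n_buckets=8,
                             n_hash_rounds=2, d_conv=128, hidden=(128, 128),
                             lr=1e-2, weight_decay=0.0, batch_size=32, grad_acc=1,
                             max_epochs=20, patience=20, pretrained=pre, seed=2022)
clf.fit(Xtr, ytr)
print(f"test accuracy {100 * np.mean(clf.predict(Xte) == yte):.1f}%")
```

Output:

```
held-out reconstruction loss 1.168 (uniform ln 7 = 1.946)
test accuracy 97.5%
```

The reconstruction loss beating ln 7 means the encoder predicts masked
expression bins better than chance from gene context; the test accuracy is
measured on cells never seen in either training stage (chance level here is
~21%, and a nearest-centroid classifier on the true planted markers scores
~96%, so the model recovers essentially all of the available signal).

The same pipeline is available from the shell:

```bash
screformer synth --seed 7 --out data/
screformer preprocess --input data/matrix.mtx --vocab data/embeddings.tsv --out tokens/
screformer pretrain --tokens tokens/ --embeddings data/embeddings.tsv \
    --d-model 32 --n-layers 2 --n-heads 2 --n-buckets 8 \
    --lr 1e-3 --batch-size 32 --max-epochs 20 --seed 2022 --out pre/
screformer finetune --tokens tokens/ --labels data/labels.tsv --ckpt pre/encoder.npz \
    --lr 1e-2 --batch-size 32 --grad-acc 1 --max-epochs 20 --seed 2022 --out model/
screformer predict  --model model/model.npz --input tokens/ --out preds.tsv
screformer evaluate --preds preds.tsv --labels data/labels.tsv --out report.json
screformer explain  --model model/model.npz --tokens tokens/ --labels data/labels.tsv \
    --cls type0 --background 50 --explain 20 --seed 2022 --out shap.tsv
```

`screformer cv` runs stratified k-fold cross-validation (mean ± SD of
accuracy and macro-F1), and `screformer run-all` chains every stage on a
small synthetic fixture. Ablation switches: `--attention full` (standard
attention instead of LSH), omitting `--ckpt` (no pre-training), omitting
`--embeddings` (random instead of Gene2vec-style initialization).

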