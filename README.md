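# dlam — multi-modal essential-protein prediction

Essential proteins are those whose loss is lethal to the organism.
Identifying them experimentally (gene knockout, RNA interference) is slow
and expensive, so computational prediction from protein-interaction
networks and functional genomics data is a long-standing problem in systems
biology. `dlam` is a Python library for predicting protein essentiality in
a yeast-scale setting from four complementary data modalities — domain
composition, subcellular localization, evolutionary conservation
(orthology), and gene expression — fused by an attention-augmented 1D
convolutional network, with an imbalance-aware evaluation protocol
(stratified cross-validation, fold-local normalization, validation-selected
decision thresholds, AP alongside ROC-AUC).

It is aimed at computational biologists who want a self-contained,
dependency-light (numpy/scipy/pandas/scikit-learn) reference implementation
of this class of model, including a synthetic-study generator so the whole
pipeline is testable without any database downloads.

## The method

**Domain features.** From binary protein–domain associations
`M_PDN ∈ {0,1}^{m×n}`, domains are compared by the Gaussian interaction
profile (GIP) kernel on adjacency columns,

    SD(d_i, d_j) = exp(−α · ‖ID(d_i) − ID(d_j)‖²),
    α = α′ / mean_k ‖ID(d_k)‖²,

and each association is propagated to similar domains:

    M_WPDN(p_i, d_j) = max_k [ M_PDN(p_i, d_k)·SD(d_k, d_j) + M_PDN(p_i, d_j) ] / 2.

Rows of `M_WPDN` are compressed to 36 dimensions by a single-hidden-layer
sparse autoencoder with the saturating-linear (Satlin) activation,
KL-sparsity penalty (weight 4, target 0.05) and L2 weight decay (0.01).

**Other modalities.** Each subcellular localization is scored by the number
of proteins it hosts; a protein's feature vector holds the scores of its
localizations (11 categories). The scalar orthology score is min–max
normalized and expanded to the powers 1…12. Gene expression enters as its
36-sample profile. Each modality carries a binary availability flag;
missing modalities are zero-filled and flagged.

**Network.** Four branches — two-conv (k5/s1, k4/s2) + max-pool for
expression and domain, single 1×1 conv for subcellular and orthology —
produce 10/10/20/20-channel maps of common length 12, concatenated to a
60×12 map, batch-normalized, convolved (30 kernels, k2/s2), refined by a
CBAM attention block (channel gate from avg/max-pooled descriptors through
a shared bottleneck, then a spatial gate from channel-pooled profiles),
max-pooled, flattened, joined with the availability flags, and classified
by fully connected layers 75 (dropout 0.3) → 35 → 2.

**Training & evaluation.** Adam (lr 0.009), batch size 20, early stopping
after 10 non-improving validation epochs with best-weight restoration,
cross-entropy loss. Stratified 5-fold CV with a 60/20/20
train/validation/test structure; z-scoring and orthology ranges are fitted
per fold on the training split only; the F1-optimal threshold is chosen on
validation. Reports accuracy, precision, recall, F-measure, ROC-AUC, and
average precision; paired t and exact Wilcoxon signed-rank tests (Holm
adjusted) compare per-fold scores between model variants.

## Worked example

```bash
python examples/04_cross_validation.py
```

generates a 500-protein synthetic study with planted class-conditional
effects (shifted expression means, boosted domain/orthology rates, biased
localizations), builds all feature blocks, and runs the five-fold CV. A run
prints, per fold and summarized:

```
mean +/- sd across folds:
  accuracy   0.768 +/- 0.297
  precision  0.670 +/- 0.264
  recall     0.871 +/- 0.110
  f_measure  0.723 +/- 0.209
  auc        0.914 +/- 0.104
  ap         0.836 +/- 0.159
```

Mean AUC ≈ 0.91 means the planted signal is recovered almost completely;
AP is the stricter summary under the ~1:3.4 class imbalance, and the
fold-to-fold spread reflects ~100-protein test folds. The other examples
cover simulation (`01`), the domain-feature mathematics on a tiny
hand-checkable input (`02`), single-split training (`03`), and
attention-ablation with paired significance tests (`05`).

A thin CLI wraps the same functions:

```bash
dlam simulate --out study/ --seed 1
dlam cv --data study/ --folds 5 --seed 1
dlam train --data study/ --out run/ --no-attention --features expression,domain
```

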