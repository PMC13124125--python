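# Methods

## Model

The classifier scores protein essentiality from four per-protein feature
sequences. The guiding assumptions are the standard ones for this problem:
essential proteins are enriched in particular domains and subcellular
compartments, are more conserved across species, tend to be more highly
expressed, and sit more centrally in the interaction network. None of the
modalities is reliable alone and none is completely observed, so the model
(a) propagates sparse domain annotations through a domain–domain
similarity kernel before embedding them, (b) learns per-modality
convolutional encoders and fuses them as channels of a single map, (c)
re-weights the fused map with channel and spatial attention, and (d) is
told explicitly which modalities were observed via availability flags.

### Domain block

With `m` proteins and `n` domains, the binary adjacency `M_PDN` yields a
GIP kernel over domains: bandwidth `α = α′ / mean_k ‖col_k‖²` and
`SD(i,j) = exp(−α‖col_i − col_j‖²)`. `α′` defaults to 1, the usual GIP
convention. The weighted matrix takes, for every (protein, domain) pair,
the maximum over domains k of the averaged propagated-plus-direct score
`(M_PDN(i,k)·SD(k,j) + M_PDN(i,j))/2`. Because the direct term is constant
in k this equals `(max_k M_PDN(i,k)·SD(k,j) + M_PDN(i,j))/2`, which is how
it is computed; the test suite pins both forms to a naive triple loop at
1e−12. Direct associations keep score exactly 1 and domain-less proteins
keep all-zero rows.

The sparse autoencoder has one hidden layer of 36 Satlin units (output
layer also Satlin), trained full-batch with Adam (lr 1e−3, 500 epochs) on
the objective MSE + (0.01/2)·Σw² + 4·KL(0.05 ‖ mean hidden activation).
The sparsity target 0.05 and the optimizer/epoch budget are this package's
choices; the hidden width, L2 weight, sparsity weight and Satlin
activation are fixed protocol constants. Biases start at 0.5 so hidden
units begin in the linear region of Satlin; initialization is
Glorot-uniform from a seeded generator, making training bit-reproducible.

### Auxiliary blocks

Subcellular localization: `SC(s) = #proteins in s`; a protein's vector has
`SC(s)` at its localizations and 0 elsewhere (11 categories by default,
zero-padded to length 12 at the model input). Orthology: the nonnegative
conservation score is min–max normalized with the *training-split* range,
clipped to [0,1], and expanded to powers 1…12 — raw scores can exceed 1
and 12th powers of unnormalized values would be numerically useless.
Expression: the 36-sample profile, used as-is before fold-local z-scoring.
Optional topology descriptors (log(1+degree), k-core index) are appended
to the flattened vector alongside the availability flags rather than given
a convolutional branch: two scalars carry no sequence structure.

### Network dimensions

Expression/domain branches: conv(6,k5,s1) → conv(10,k4,s2) → maxpool(k4,s1)
takes length 36 to 32 → 15 → 12. Subcellular (padded 11→12) and orthology
branches: conv(20,k1,s1) preserves length 12. Fusion concatenates channels
in the order expression, domain, subcellular, orthology (60×12). Head:
batch norm → conv(30,k2,s2) → Leaky ReLU (slope 0.01) → CBAM → maxpool(k2,s2)
→ flatten (30·3 = 90) → +flags → FC 75 (dropout 0.3) → FC 35 → 2, softmax.
The pooling sizes, the common length 12, the CBAM reduction ratio (2) and
spatial kernel (3, symmetric padding — the map is only 6 long), the Leaky
ReLU slope, and the flag-injection point (after flattening, keeping the
convolutions purely biological) are the minimal arithmetic consistent with
the fixed kernel/stride/width constants; each is exposed in `ModelConfig`.

The network runs on an in-package reverse-mode autodiff core
(`dlam._autograd`): a tape-based numpy `Tensor` with conv1d/maxpool
implemented via stride tricks and every op's backward checked against
central finite differences in the test suite. Model construction, batch
shuffling, and dropout masks all draw from seeded generators, so
(seed, config, data) determines every reported number exactly.

## Training protocol

Adam at lr 0.009, batch 20, cross-entropy; early stopping when the
validation loss has not improved on its running best for 10 consecutive
epochs ("no strict improvement" semantics), with the best-validation
weights restored; max 300 epochs (in practice the planted-signal studies
stop near epoch 15–30). Optional random undersampling keeps all positives
and draws `floor(n_pos·ratio)` negatives without replacement. The decision
threshold maximizes validation F1 over a 101-point grid, ties broken
toward 0.5; a single-class validation split falls back to 0.5. Class
weighting is off by default (an optional weighted loss exists in config).

## Evaluation protocol

Stratified k-fold (default 5) with per-fold class counts within 1 of exact
proportion; inside each development set a stratified 75/25 train/validation
split gives a 60/20/20 overall structure. Normalization (z-scores;
constant features map to 0) and the orthology range are fitted on the
training split only — permuting held-out rows provably changes neither the
normalizer nor the trained weights, and this is asserted in tests. Scalar
metrics use the zero-denominator convention (precision/recall/F = 0).
ROC-AUC (trapezoid) and step-interpolated AP come from scikit-learn and
are cross-checked against pairwise-comparison and cumulative-sum oracles.
Paired comparisons on per-fold scores use the paired t-test (p guarded to
1 for identical vectors) and an exact Wilcoxon signed-rank test whose null
distribution is built by dynamic programming over signed midranks — exact
enumeration remains valid under tied differences, where the usual exact
routines refuse — with Holm step-down across the comparison family.

## Synthetic studies

The generator emits the full six-file bundle plus ground truth. Defaults:
1,000 proteins, 150 domains, 11 localizations, 36 expression samples,
prevalence 0.23 (the ~1:3.4 positive:negative ratio typical of curated
yeast benchmarks), 0.9 per-modality coverage. Planted effects: expression
mean shift +0.5 sd per sample for essentials, domain association rate ×2,
orthology Poisson rate +2 on a base of 3, doubled preference for the
"essential-prone" half of the localizations, and a ×1.5 Chung-Lu degree
weight (the centrality–lethality correlation). Proteins present in an
association source always have at least one association, so availability
flags coincide with the planted coverage. Everything is drawn from one
seeded generator and files are written with fixed formatting, so a config
is byte-reproducible.

What the generator does **not** emulate: time-course autocorrelation in
expression, domain co-occurrence structure, localization hierarchies, or
assortative PPI noise. Passing the recovery tests therefore shows that the
pipeline's plumbing, training loop, and protocol are sound — not that the
architecture would reach any particular performance on real DIP/BioGRID
data.

## Problem sizes and numerical choices

The acceptance script uses the default 1,000-protein study for the
five-fold CV and five 400-protein zero-effect studies for the null
calibration, with the autoencoder at 150 epochs for the nulls; these sizes
give stable estimates (test folds of ~175 and ~80 proteins) at desk-scale
runtime. Probabilities in the loss are clamped at 1e−12; batch-norm ε is
1e−5; the sigmoid uses the numerically stable two-branch form. The PPI
universe defines the label set, so proteins that end up with no
interactions drop out of the study (a 1,000-protein config yields ~870
network proteins).

## Known limitations

* The literal weighted-matrix construction is O(m·n·deg); fine at 10³–10⁴
  domains, not tuned beyond that.
* The exact Wilcoxon enumeration is exact for any n but the DP table grows
  with the squared sum of ranks; it is intended for fold counts (n ≤ 25).
* Batch-norm running statistics are seeded from the first training batch
  and then tracked with momentum 0.1; with very few training batches
  eval-mode outputs can still differ noticeably from training-mode
  behavior. Relatedly, at the protocol's fixed learning rate the validation
  loss can peak within a handful of epochs on few-hundred-sample training
  splits, so early stopping sometimes restores a lightly trained model and
  individual CV folds show visibly weaker AUC than their neighbors.
* No GPU path; the autodiff core is single-threaded numpy. A full
  1,000-protein five-fold CV takes well under a minute on one CPU core.
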