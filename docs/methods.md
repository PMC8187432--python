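# Methods

This document describes the model implemented by the `mogonet` package, the
assumptions behind it, the meaning and defaults of its parameters, and the
numerical and design choices that shape its behaviour.

## Problem setting

Given m omics views (e.g. mRNA expression, DNA methylation, miRNA
expression) measured on the same n samples, each with its own feature set,
and a class label per sample, the task is supervised classification of the
samples plus identification of the features that drive the classification.
The method is transductive: a new sample is classified by attaching it to
the training samples' similarity graph, not by an inductive feed-forward
pass alone.

## Model

### Per-view similarity graphs

Each view induces a weighted graph on the samples. The edge weight between
samples i and j is their cosine similarity s(x_i, x_j), retained when
s ≥ ε and set to zero otherwise; the diagonal is zero. The threshold ε is
set implicitly by an interpretable parameter k, the average number of
retained pairs per node counting self-pairs: ε is the (k·n)-th largest of
the n² similarity values, i.e. the largest threshold whose average retained
count is still at least k. Ties at ε are all retained.

The retained adjacency A is renormalized with self-loops,

    Ã = D̂^{-1/2} (A + I) D̂^{-1/2},   D̂ = diag(rowsums(A + I)),

which keeps all eigenvalues of Ã in [−1, 1] and hence graph-convolution
propagation stable. This bound, and the positivity of every degree, relies
on nonnegative edge weights; the pipeline guarantees this because features
are scaled to [0, 1] (so cosine similarities are ≥ 0), and the graph code
rejects negative weights explicitly.

With k = 1 only self-pairs survive, A = 0, Ã = I, and every graph
convolution degenerates to an ordinary fully connected layer — the formal
link between the full model and its graph-free ablation.

### Per-view GCN classifiers

Each view gets a graph convolutional network: hidden layers compute
σ(Ã H W + b) with a leaky rectifier (negative slope 0.25), inverted dropout
(rate 0.5) on hidden activations during training, followed by a linear
class-score head. Weights use scaled uniform (Xavier) initialization.

### Cross-omics integration (VCDN)

Each view's class probabilities (softmax of its GCN scores) enter an
m-way outer product per sample, the cross-omics discovery tensor with c^m
entries (c classes), flattened with the first view slowest-varying. A fully
connected network (one hidden layer of the same width by default) maps the
flattened tensor to final class scores. For c = 2, m = 3 the tensor input
has 2³ = 8 entries, versus 2·3 = 6 for plain concatenation.

### Training

All losses are class-weighted cross-entropies; the weight of class c is the
inverse training frequency, normalized to mean one, and the loss is averaged
over samples (mean reduction — a design choice that makes learning rates
insensitive to n; the weighting is equivalent up to a constant factor to
summing per-sample weighted terms). Training proceeds in two phases:

1. **Pretraining**: each GCN is trained alone on its view for
   `pretrain_epochs` full-batch Adam steps.
2. **Joint training**: for each of `joint_epochs` epochs, first the GCNs
   take one Adam step on the total loss
   L = Σ_i L_GCN^(i) + γ·L_VCDN (γ = 1 by default), then the integration
   head takes one step on the recomputed loss with the GCNs fixed.

Optional early stopping monitors the change of the joint loss
(`loss_tol`, `patience`).

### Transductive prediction

Each test sample is appended to the training graph on its own: only its
similarity row against the training samples is computed, thresholded with
the training ε, and the (n+1)-node graph is renormalized; the GCN forward
pass over this extended graph yields the test sample's probabilities. The
per-sample extension is the default because it makes each prediction
independent of which other test samples are present; a `batch` mode that
appends all test samples at once (without test–test edges) is available
for comparison. The batched implementation is bitwise identical to an
explicit per-sample loop. A test sample that duplicates a training sample
receives (near-)identical probabilities to that training node.

### Ablation variants

- `mogonet` — GCN classifiers + tensor head (the full model)
- `mogonet_nn` — GCN classifiers + concatenation head
- `nn_vcdn` — fully connected classifiers + tensor head
- `nn_nn` — fully connected classifiers + concatenation head

The fully connected variants are implemented as GCNs over the identity
graph, so at k = 1 `mogonet` and `nn_vcdn` coincide bitwise (identical
initialization streams are keyed by view name, not variant).

With a single view there is no integration head; the model is the view's
GCN alone.

## Preprocessing

Per view, fitted on training rows only:

1. **Variance filter**: drop features with population variance below a
   per-view threshold, or with zero mean. Typical thresholds: 0.1 for
   expression-scale data, 0.001 for beta-value-scale data; default 0.0
   (drop only exact constants and zero-mean features).
2. **ANOVA preselection**: rank features by the one-way ANOVA F statistic
   across classes; control the false discovery rate with the
   Benjamini–Hochberg procedure at α = 0.05; keep the top `n_keep`
   significant features. The default keeps all variance-surviving features
   (`"all"`), so downstream biomarker ranking covers the full panel; real
   high-dimensional data should set explicit counts.
   `choose_feature_count` automates the choice over a grid (default
   {200, 1000, 2000}): it takes the smallest count whose selected panel has
   a first principal component explaining less than half the variance,
   avoiding panels dominated by one redundant signal direction.
3. **Scaling**: min-max scale each feature to [0, 1] using training
   minima/maxima; held-out samples are transformed with the training map
   and clipped into [0, 1].

## Biomarker ranking

A feature's importance is the drop in held-out performance (F1 for binary
tasks, macro-averaged F1 otherwise) when its test-set values are set to
zero — meaningful because inputs live in [0, 1], where zero is the signal-
free level; unscaled inputs are rejected. Only test rows are zeroed; the
fitted model and training graph are untouched. By default the ablated
feature also enters the recomputation of the test samples' similarity
rows, since the graph is part of the prediction path
(`recompute_graph=False` freezes it). Drops are summed over `n_repeats`
(default 5) independent stratified train/test splits with retraining, then
scaled by the view's preselected feature count so views with different
panel sizes compete fairly, and ranked globally. Negative drops (ablation
helped) are kept. Columns that are already all zero score exactly 0.

## Synthetic data

The generator draws class-conditional Gaussians per view and scales each
feature to [0, 1]. Each view has a set of "marked" classes: for a marked
class, the first `n_informative` features receive a mean shift of
±(effect_size · noise_sd) with a fixed random sign pattern per class;
unmarked classes are indistinguishable within that view. The
complementary-trio configuration (three views, view i marks only class i)
is the canonical integration benchmark: no single view separates all
classes, so integration has measurable headroom. The generator emulates
block-structured class signal in independent Gaussian noise; it does not
emulate omics-specific marginal distributions (methylation beta values,
count overdispersion), feature–feature correlation, or batch effects.
Everything is determined by the seed, and the planted feature names are
returned as ground truth.

## Determinism and numerics

- All randomness flows from one master seed, fanned out into named
  substreams (one per purpose: splits, per-view initialization, dropout,
  each synthetic component) via hash-derived spawn keys, so adding a
  consumer never shifts another's stream, and derived seeds stay below
  2³¹.
- Neural-network training uses a small reverse-mode automatic
  differentiation core over numpy arrays with explicit Adam updates;
  gradients are verified against central finite differences in the test
  suite. Full-batch updates are used throughout (transductive graphs
  preclude mini-batching).
- Cosine similarities are clipped to [−1, 1], symmetrized, and given an
  exact unit diagonal, so thresholds behave predictably at the
  self-similarity boundary.
- Softmax and log-softmax are computed with max-subtraction for stability.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `k` | `"auto"` over {2, 5, 10} | average retained similarity pairs per node; tuned by 5-fold cross-validated accuracy (ties to the sparser graph) |
| `gamma` | 1.0 | weight of the integration loss in joint training |
| `gcn_hidden` | [400, 400] | GCN hidden widths (sized for high-dimensional panels; smaller problems should shrink them) |
| `vcdn_hidden` | input width | integration-head hidden width |
| `activation_slope` | 0.25 | leaky-rectifier negative slope |
| `dropout` | 0.5 | hidden-layer dropout rate during training |
| `lr_pretrain`, `lr_gcn`, `lr_vcdn` | 1e-3, 5e-4, 1e-3 | Adam step sizes per phase |
| `pretrain_epochs`, `joint_epochs` | 500, 1000 | training lengths (full-batch epochs) |
| `fdr_alpha` | 0.05 | Benjamini–Hochberg level for preselection |
| `preselect_grid` | [200, 1000, 2000] | candidate panel sizes for `choose_feature_count` |
| `pc1_max_fraction` | 0.5 | PC1 variance-fraction bound in panel-size choice |
| `test_fraction`, `n_repeats` | 0.30, 5 | evaluation-protocol split size and repeat count |

The package's own benchmarks (tests and the acceptance script) run scaled-
down problems — 300 samples, 3 classes, 200 features per view, hidden
widths 64 — chosen so the full property suite completes in minutes on one
CPU while leaving the assessed properties (integration benefit, degeneracy,
biomarker recovery, transductive consistency) intact.

## Known limitations

- Training is full-batch and dense (n × n graphs); the implementation
  targets cohort-scale n (hundreds to a few thousand samples), not
  biobank scale.
- The model is transductive: predictions depend on the training cohort's
  graph, and the training matrices are part of the persisted model.
- The autodiff core implements exactly the operations these networks need;
  it is not a general deep-learning framework and runs on CPU only.
- Zero-ablation importance measures marginal contribution one feature at a
  time; tightly correlated features share credit and can mask each other.
- The evaluation protocol (repeated stratified splits) estimates mean
  performance; it does not provide confidence intervals beyond the
  across-repeat standard deviation.
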