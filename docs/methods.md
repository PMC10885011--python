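# Methods

## Task and data model

The package addresses two-layer enhancer prediction on fixed-length DNA
fragments: layer 1 separates enhancers from non-enhancers; layer 2
separates strong from weak enhancers among the layer-1 positives. Inputs
are FASTA records over {A, C, G, T, N}; labels are attached per file of
origin through a `manifest.yaml` mapping each FASTA file to a
(task, split, label) triple. The canonical benchmark has 2,968 core
identification sequences (balanced), 742 strong + 742 weak core
enhancers and a 100/100 independent strength test set; the loader checks
these counts and *warns* (rather than fails) on mismatch so that subsets
remain loadable. `N` residues are accepted at load; k-mers containing
them map to the unknown token downstream. The independent identification
split's non-enhancer file is treated as optional because distributions of
the data differ on whether it exists; the loader reports what it finds.

## Tokenization

Sequences are decomposed into overlapping k-mers at stride 1 (a
non-overlapping mode exists but is off by default), giving
L − k + 1 tokens per sequence. The vocabulary is corpus-derived — its
size is the number of distinct observed k-mers plus three specials
(`<pad>`, `<unk>`, `<bos>`) — with full 4^k enumeration available by
flag. `<bos>` is prepended for language-model training so the first real
k-mer has a prediction context; `<pad>` is used only for batching and is
masked out of the loss.

## Language model

The encoder is a next-k-mer language model:

* **Stochastic embedding layer.** E ∈ ℝ^{|vocab| × d}, d = 400 by
  default. During training whole token vectors are zeroed with
  probability p_embeddings and individual components of the survivors
  with p_embeddings_dim (both default 1e-3, the selected optimum).
  Dropped values are replaced by zeros without rescaling; at 1e-3 the
  expectation shift is negligible. Evaluation is an exact lookup.
* **Three weight-dropped LSTM layers**, 256 hidden units each. Gates:
  I_u = σ(W^i x_t + U^i h_{t−1} + b_u), I_f and I_o analogous,
  cin_t = tanh(W^c x_t + U^c h_{t−1}) (no bias on the candidate path;
  an optional cell bias exists but defaults off),
  c_t = I_u ⊙ cin_t + I_f ⊙ c_{t−1}, h_t = I_o ⊙ tanh(c_t).
  DropConnect zeroes elements of the gate matrices [W^i, W^f, W^o] and
  [U^i, U^f, U^o] with probability 0.4; one mask is drawn per batch and
  shared across all time steps of the forward and backward pass. The
  candidate-path matrices W^c, U^c are not masked.
* **Decoder.** A plain affine map from the 256-dim hidden state to
  vocabulary logits. Embedding-weight tying is not used: the embedding
  (400) and hidden (256) widths differ, which rules out standard tying.

Training minimises masked next-token cross-entropy with Adam
(decoupled weight decay, applied to matrices only). Defaults follow the
grid-search optima: lr 1e-4, weight decay 1e-2, batch 64, early-stopping
patience 50. A seeded 10% held-out split drives early stopping and the
best-validation parameters are restored, so the final held-out loss
never exceeds the initial one. Backpropagation-through-time runs over
the full token sequence (≤ ~200 steps — short enough that no truncation
is needed). Non-finite loss aborts with a diagnostic. Fine-tuning
continues the same objective on the task corpus with the vocabulary
frozen (unseen k-mers map to `<unk>`); `max_epochs=0` is a no-op.

`encode()` returns the **final LSTM layer's hidden state at every token
position** in evaluation mode (no stochastic layers). The classifier
consumes these states rather than raw embeddings: the representations
handed to the classifier are the ones produced by the trained language
model, and the last layer is where its context aggregation lives.

The pretraining corpus is, by default, the (unlabeled) training-fold
sequences of the task at hand — no external corpus is assumed.
Discriminative per-layer learning rates and gradual unfreezing are not
implemented; fine-tuning uses a single rate.

## Classifier head

Per-position encoder states pass through:

1. **Convolution.** A^{[l]} = ReLU(A^{[l−1]} ⊗ W^{[l]} + b^{[l]}):
   valid-mode (no padding) 1-D cross-correlation; default one layer of
   30 filters of width 3. 30 filters is the selected optimum (the
   search space runs 10–50, and deeper 2–3 layer stacks are supported
   and swept by the grid search).
2. **Scaled dot-product attention.** Q, K, V are separate learned
   affine projections of the conv features (d_k = number of filters);
   Weight = softmax(QKᵀ/√d_k) is square with side equal to the number
   of conv output positions and row-stochastic; output = Weight·V.
3. **Pooling.** The per-position attention output is mean-pooled into
   one vector per sequence (the attention output has no designated
   summary position, so some pooling rule is required; an
   attention-weighted sum variant is available via `pooling=
   "attention_sum"`).
4. **Batch normalization.** Per-feature standardization by mini-batch
   moments in training (μ = Σz_i/m, σ² = Σ(z_i−μ)²/m,
   ẑ = (z−μ)/√(σ²+ε), y = γẑ + β, ε = 1e-5), by running moments at
   evaluation. After training, the running moments are *recalibrated*
   to the pooled statistics of the full training set, which makes
   thresholded predictions independent of the momentum schedule.
5. **Inverted dropout.** Keep probability 1−p with 1/(1−p) rescaling;
   identity at evaluation. Task defaults: p = 0.01 (identification),
   p = 0.1 (strength).
6. **Affine softmax** with categorical cross-entropy
   L = −Σ y_i log(ŷ_i); a 1e-12 probability floor guards the log.

Head training: Adam with task-specific optima (identification:
lr 1e-3, wd 1e-4, patience 5; strength: lr 2e-2, wd 5e-3, patience 7),
batch 64, stratified 10% internal validation split for early stopping,
best-validation restore. The encoder is **frozen** during head training;
task adaptation of the encoder happens in the fine-tuning stage. Hard
labels use a 0.5 threshold on the positive-class probability.

All gradients are derived and implemented by hand; the test suite
verifies them against central finite differences (1e-4 relative) and
verifies each primitive against an independent brute-force evaluation
(1e-10).

## Evaluation protocol

`compute_metrics` reports TP/TN/FP/FN at the threshold plus
ACC = (TP+TN)/n, SN = TP/(TP+FN), SP = TN/(TN+FP) (percentages),
MCC = (TP·TN − FP·FN)/√((TN+FN)(TN+FP)(TP+FN)(TP+FP)) (0 when a
marginal is empty), AUROC as the ROC curve integral (equal to
Mann–Whitney concordance) and AUPRC as the step-wise precision–recall
integral (average precision). The threshold-bound closed form
(SN+SP)/2 is additionally reported as *balanced accuracy* for
transparency — it is not a substitute for the curve integrals.
Single-class truth vectors yield NaN AUROC/AUPRC with a warning.
A predictor is flagged *type-1-prone* (excess false positives) when
SN − SP > 5 points, *type-2-prone* when SP − SN > 5, otherwise
*unbiased*.

Cross-validation is stratified k-fold (default 5), deterministic under
the seed, with per-fold class ratios within one example of the global
ratio. By default the language model is pretrained **per fold** on that
fold's training sequences only, so no held-out information reaches the
encoder; a `shared` mode reusing one encoder across folds exists for
comparison with protocols that train the encoder once on all core data
(that variant is leakage-prone and is not the default). Fold metrics
are aggregated as unweighted means.

Grid search sweeps head hyperparameters over candidate lists (the
documented search spaces are in `CLASSIFIER_SEARCH_SPACE` /
`LM_SEARCH_SPACE`), scores each candidate on a stratified validation
split, and ranks by validation MCC with ACC and then smaller parameter
count as tie-breaks; a budget caps the number of candidates, drawn from
a seeded shuffle of the exhaustive grid. Diverging candidates are
recorded with −∞ score instead of aborting the sweep.

Default k-mer sizes per task: k = 2 for identification; k = 3
(independent-test protocol) or k = 4 (cross-validation protocol) for
strength — the sizes at which each task peaks — all configurable.

## Synthetic data generator

The generator emulates the compositional class structure of real
enhancer data: the positive class (enhancer / strong) is drawn i.i.d.
with P(G) = P(C) = gc_positive/2; the negative class (non-enhancer /
weak) uses gc_negative plus a first-order Markov boost multiplying the
A→A and T→T self-transition probabilities by (1 + homopolymer_boost),
which plants the AA/AAA/TT/TTT run excess characteristic of
non-enhancer sequences. Defaults: length 200 (matching the benchmark),
GC 0.60 vs. 0.40 in easy mode and 0.52 vs. 0.48 in hard mode,
homopolymer boost 0.5 — a visible but not overwhelming run excess.
Generation is byte-deterministic under the seed and emits the same
dataset type as the benchmark loader.

What the generator does **not** model: enhancer motif grammar,
positional structure, chromatin context, genome background, and any
dependence beyond first order. Passing tests on synthetic data
therefore demonstrate that the pipeline recovers compositional and
dimer-scale signal and that its machinery (training, CV, metrics) is
correct — not that it attains any particular performance on real
enhancer data, which carries far subtler signals.

## Numerical choices

* float32 for language-model training (memory/speed of BPTT over ~200
  steps); float64 for the classifier head and all oracle-checked
  primitives. The public cell/layer functions compute in their input
  dtype.
* Stable softmax (max-shift) everywhere; sigmoid split by sign;
  probability floor 1e-12 inside logs.
* Adam: β = (0.9, 0.999), ε = 1e-8, decoupled weight decay on
  matrices only (biases and gains undecayed).
* Initialisation: uniform ±1/√H for LSTM weights, uniform ±0.1
  embeddings, ~0.01-scale decoder — so an untrained model's
  cross-entropy starts at ≈ ln |vocab|.
* Early stopping counts epochs without strict validation improvement;
  ties count as no improvement.
* Batch-norm batches of size 1 are skipped during training (their
  variance is degenerate); the internal validation split keeps at least
  one example per class via stratification.

## Problem sizes in tests and the acceptance script

Training-based checks run at reduced encoder scale — 32–64-dimensional
embeddings and hidden units rather than the 400/256 defaults — on
synthetic datasets of 150–400 sequences per class. The planted signals
are strong relative to model capacity, so the qualitative outcomes
(signal recovery, chance-level null, ablation direction, k-mer ranking)
do not depend on the reduction; the full-size configuration is the
package default and runs unchanged, just longer.

## Known limitations

* Pure-NumPy training is single-threaded beyond BLAS; full-size
  (400/256 × 3 layers) pretraining on thousands of sequences takes
  minutes per epoch on one CPU.
* Batch normalization follows the printed mini-batch formulation; a
  layer-norm variant is not provided.
* No multi-head attention, positional encodings or masked-LM
  objectives — the architecture is deliberately the single-attention
  CNN head over an AWD-LSTM encoder.
* The benchmark loader expects pre-extracted fixed-length sequences;
  there is no genomic-coordinate (BED/GFF) support and no download
  client.
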