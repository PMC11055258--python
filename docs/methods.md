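# Methods

This note documents the models, estimators and numerical choices behind
`wmigcn`, the assumptions they rest on, and what the bundled synthetic
experiments do and do not demonstrate.

## Mutual-information lead graphs

Each 12-lead record is treated as a 12-variable time series. Dependence
between leads i and j is quantified by mutual information in bits,
computed through the entropy identity I = H(Xᵢ) + H(Xⱼ) − H(Xᵢ, Xⱼ) with
plug-in (maximum-likelihood) entropies over an equal-width discretization
of each lead.

* **Bins (`mi.n_bins`, default 16).** Equal-width binning spans
  [min, max] of each lead; the maximum falls in the last bin and a
  constant lead maps to a single symbol. 16 bins on 2 500–5 000 samples
  keeps the plug-in bias moderate (the test suite bounds the
  independent-lead bias at <5% of the marginal entropy at T = 5000).
  The estimator is the simplest faithful realization of the discrete MI
  formulas; k-NN/Kraskov style continuous estimators are out of scope.
* **Clamping.** The identity can go infinitesimally negative in floating
  point; MI is clamped at 0, which is exact mathematically.
* **Diagonal.** I(X; X) = H(X), so the MI matrix diagonal holds the
  marginal entropies.

The WMI adjacency multiplies MI entries by (1 + r), where r = 1 when the
two leads share a pole cluster (bipolar limb I/II/III, augmented unipolar
limb aVR/aVL/aVF, precordial V1–V6): same-cluster edges are exactly
doubled, cross-cluster edges unchanged. Each record yields its own graph;
no population-average adjacency is formed.

## Adjacency preprocessing for training

Polynomial filters involve powers A^k, so raw MI magnitudes (up to ~2·H ≈ 8
for WMI entries) must be controlled. Three modes are provided
(`adjacency.normalize`):

* `spectral` — divide each matrix by its own spectral radius (classical
  GCN normalization; implemented by `normalize_adjacency`).
* `dataset` (training default) — divide **all** matrices by one constant,
  the mean spectral radius of the zero-diagonal MI graphs of the
  collection. Per-record spectral normalization forces every graph to the
  same scale and thereby erases between-record magnitude differences; when
  coupling strength varies by rhythm class those differences are class
  information, so the shared constant keeps them while still bounding the
  powers. The constant is fitted on the MI graphs and shared by the WMI
  variant, so the (1 + r) weighting acts on the scaled MI exactly as
  written and WMI retains its doubled within-cluster magnitudes.
* `none` — raw matrices.

`zero_diagonal` (training default: on) removes the entropy diagonal before
scaling. The filter's h₀·I term already learns each node's
self-connection, and the diagonal is a large self-loop that is nearly
constant across classes, so dropping it improves the signal-to-nuisance
ratio of the graph. The bare matrix-construction operations keep the
diagonal by default, per the defining formulas.

## The graph convolutional classifier

A filter of order K (default 2 — two-hop neighborhoods suffice on a dense
12-node graph) is H = Σ_{k≤K} h_k A^k, evaluated by Horner's scheme, with
an independent coefficient per (input-channel, output-channel) pair. A
layer computes the filter bank output plus bias, a rectifier, and dropout.
Node features Z₀ are the lead signals resampled to
`node_feature_length` samples (decimation when the ratio is integral,
linear interpolation otherwise) and standardized per lead; constant leads
map to zeros.

The readout concatenates the node embeddings of three retained depths —
Z₀, a middle layer and the last layer (all depths when ≤2 layers) — in two
stages: channel-wise concatenation per node, then flattening across the 12
nodes, followed by one fully connected softmax layer. Tapping three depths
generalizes the multi-scale readout to deep stacks without quadratic
growth in readout width.

Training minimizes mean cross-entropy full-batch with Adam and decoupled
weight decay (lr 0.02, weight decay 5e-4, dropout 0.2, patience 10, up to
600 epochs by default). Biases are not decayed. Early stopping monitors
validation loss (training loss when no validation set is supplied) and
restores the best-loss weights. The whole network is NumPy with
hand-derived backpropagation; correctness is enforced by finite-difference
gradient checks, a linearity property for the convolution, and an exact
collapse test: with the identity adjacency, A^k = I and the network must
equal a per-node multilayer perceptron with collapsed weights Σ_k W_k.
One master seed drives weight initialization and dropout, making training
bit-for-bit reproducible; plain gradient descent at the same learning rate
was evaluated and fails to train at desk scale, which is why the adaptive
scheme is the default.

## Evaluation protocol

Classes with frequency below `eval.min_class_fraction` (default 2%) of the
**pre-filter** total are removed; the boundary is a strict less-than, and
fractions are judged once, before any removal. A single-class input is
rejected; a filter result with one surviving class is allowed (the
downstream fit then rejects it). Folds are stratified (per-class fold
counts differ by ≤1), deterministic per seed, and shared across adjacency
variants so the comparison isolates the graph structure. Every record is
predicted by the model of the fold that held it out; per-class one-vs-rest
sensitivity, precision, specificity and accuracy are computed from the
pooled confusion matrix, with 0/0 reported as NaN markers excluded from
the macro average. Variants are compared pairwise with the equal-variance
independent two-sample t-test on fold accuracies (df = 2k − 2); zero
pooled variance is reported as t = 0, p = 1 for equal means and an
infinite-t marker with p = 0 otherwise. No multiple-testing correction is
applied. Aggregate metrics are reported as mean ± per-fold SD on the
proportion scale.

## Synthetic generator

Each record is lead_i(t) = gain_i·[β·g(t) + α·s_c(i)(t) + (1−α−β)·ε_i(t)]
with unit-variance sources: g a 3-harmonic stack at the class beat rate
with per-record random phase; s_c three independent low-pass (8 Hz
Butterworth) noise processes shared within each pole cluster; ε_i
lead-private noise with the **same** low-pass spectrum. The shipped
classes are bradycardia-like (1.0 Hz, α = 0.5), normal-rate (1.3 Hz,
α = 0.5) and tachycardia-like (2.0 Hz, α = 0.6), with β = 0.3, T = 2500
samples at 250 Hz, and one named random stream per record derived from the
master seed (reproducible under partial regeneration).

Two choices are deliberate and load-bearing:

* **Random beat phase.** With coherent phase, classes are separable from
  raw time-domain templates and every classifier — including the
  structure-blind identity baseline — is perfect, making the comparison
  vacuous. Random phase removes the template shortcut while leaving the
  spectral peak (so a trivial dominant-frequency classifier still reaches
  ≥90%, confirming the task is not impossible).
* **Band-limited private noise.** With white private noise, the
  within-cluster correlation is arithmetically mirrored in each lead's own
  white-noise share, so single-lead marginals leak the class signal and
  the identity baseline matches the graph models. Matching the private
  noise spectrum to the cluster sources makes single-lead marginal
  spectra identical across classes up to the beat-line position; the
  classes then differ (almost) only in inter-lead structure — precisely
  what the lead graph is meant to capture.

What the synthetic experiments show: that the pipeline detects planted
within-cluster coupling, that the WMI weighting improves on raw MI when
within-cluster coupling is the discriminant, and that ignoring lead
structure loses most of the signal. What they do not show: performance on
real ECG morphology (PQRST waveforms, fibrillatory waves, electrode
artifacts), robustness to the denoising pipeline of real datasets, or the
absolute accuracy levels reachable with ~10k real records — the two
rate-only-separated synthetic classes are intentionally near-confusable,
which caps accuracy around two thirds in the desk-scale study.

## Desk-scale study configuration

The bundled comparison study uses 300 records (100 per class), 4-fold
stratified CV, 5-layer networks with 32 hidden channels, K = 2,
feature length 250, up to 100 epochs, and five master seeds. These sizes
were chosen to exercise the full pipeline at workstation scale; the
configuration was selected on a disjoint set of design seeds before being
frozen. Larger networks (10/15 layers, feature length up to the full
record) are supported through configuration.

## Known limitations

* The plug-in MI estimator is biased upward at small T; the bias is
  quantified but not corrected (bias-corrected or continuous estimators
  are out of scope).
* Early stopping uses the test fold as the validation monitor inside the
  cross-validated study, as is common in compact CV protocols; fold
  accuracies are therefore mildly optimistic, identically so for all
  variants, leaving the comparison unbiased.
* The dataset-level scale constant is computed over the full record
  collection (an unsupervised scalar); computing it on training folds only
  changes results negligibly but is not the default.
* Single-lead (wearable) ECG, spectral GCN variants, attention, and
  time-lagged or partial information measures are out of scope.
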