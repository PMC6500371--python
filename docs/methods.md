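# Methods

This note documents the models, the synthetic data conditions, the
numerical choices and the limitations of `sargnet`. It states no result
the test suite or `scripts/acceptance.py` does not itself compute.

## The classification problem

Each observation is one 1-km coastal MODIS pixel described by 14
dimensionless reflectances: surface reflectance ρs and top-of-atmosphere
reflectance ρt at 412, 469, 555, 645, 859, 1240 and 2130 nm, with a
binary label (1 = *Sargassum* present). The spectral contrast between
classes is small and concentrated in the NIR/SWIR bands (859 and
1240 nm, the bands the Floating Algae Index exploits), which is why
capacity-rich classifiers with strong regularization are used rather
than a single index threshold.

## Architectures

All three classifiers end in a 2-unit softmax trained with categorical
cross-entropy; feature vectors are ordered [ρs 412→2130, ρt 412→2130]
and consumed either as one 14-long single-channel signal (default) or
as a 7-long two-channel signal (ρs/ρt as channels).

**ERISNet.** Nine 1D convolutional blocks whose (filters, kernel)
sequence repeats the motif (64, 8), (128, 5), (128, 3) three times.
Each block is conv → ReLU → batch norm → dropout, with an L2 penalty on
the conv weights (the squared-magnitude penalty added to the loss).
The conv stack feeds two 64-unit LSTM blocks — the first emits the full
hidden sequence, the second its final state — each batch-normalized,
then the softmax head. Design points that were genuinely open:

* *Nine blocks vs a three-entry filter list*: the only reading
  consistent with both statements is motif repetition; we repeat the
  printed (64, 8), (128, 5), (128, 3) motif three times.
* *Same-length padding*: kernels of width 8 on a length-14 signal would
  otherwise collapse the sequence axis long before nine blocks; padding
  is (k−1)/2 left (floor) and k/2 right.
* *Unpublished rates*: conv-block dropout defaults to 0.2 and the L2
  coefficient to 1e-3; both are configurable.
* *Head*: a single dense softmax of width 2, with no hidden dense
  layers before it.

**MLP.** 14 → 500 → 500 → 500 → 2; hidden layers ReLU with dropout
(0.2, 0.2, 0.3). The closed-form parameter count Σ (fan_in + 1)·fan_out
is 509,502 and is asserted against the built network.

**FCN.** Conv blocks (128, 8), (256, 5), (128, 3) in conv → BN → ReLU
order (the stated block equations put normalization before the
activation), global average pooling over the sequence axis, softmax
head.

## Training and evaluation protocol

Mini-batch gradient descent with Adam (lr 1e-3, β = 0.9/0.999; the
optimizer was not published — Adam is this stack's conventional
default). One epoch is one full seeded-shuffled pass over the training
set in batches of 100; no early stopping. Inputs are raw reflectances
by default, with an optional per-feature z-scoring fitted on the
training split.

Evaluation preserves the published asymmetry: the MLP and FCN are
scored on a stratified 50/50 split (per class, ⌈fraction·n⌉ pixels go
to the training side), while ERISNet is scored by stratified 5-fold
cross-validation, summarized by the mean per-fold accuracy
MPCE_k = (1/k) Σ e_i/c_i with e_i the correctly classified count and
c_i the size of fold i. A `protocol` switch runs all models under
either scheme. Hard calls are the argmax of the softmax; a predicted
probability of exactly 0.5 is assigned to class 0 (documented
tie-break). Fold assignment spreads per-class remainders to the
currently smallest folds, so 4,515 pixels at k = 5 give five folds of
exactly 903.

## Neural-network engine

The layers are implemented in float64 numpy with hand-written reverse
mode: dense, 1D conv (im2col), batch normalization, inverted dropout,
LSTM (gate order i, f, g, o; forget bias 1; full backprop through
time), global average pooling. Initialization is Glorot-uniform with
zero biases; all randomness (initialization, dropout masks, batch
shuffling, splits, folds) derives from user-supplied seeds through
`numpy.random.SeedSequence`, so every pipeline is bit-reproducible on a
single platform (cross-platform bit-exactness is not promised).

Batch normalization uses batch statistics in training and
bias-corrected exponential running averages in eval (momentum 0.9, the
zero-initialized averages divided by 1 − momentum^t, ε = 1e-3). The
bias correction matters here: with only a handful of batches per epoch,
uncorrected running averages stay badly biased for tens of epochs and
eval-mode predictions are meaningless even while training-mode accuracy
is high.

Degenerate inputs: empty classes and empty test sets raise explicit
no-data errors rather than returning silent zeros; a non-finite
training loss aborts with the epoch and batch named; reflectance cells
that fail to parse report their row index.

## Synthetic data conditions

The generator emulates the labeled study table. Class c's pixels are
drawn as μ_c + s·(√ρ·z₀·1 + √(1−ρ)·z), with z₀ a scalar standard
normal shared by all 14 bands of a pixel (a common factor: haze, glint
and water brightness move all bands together), z independent per band,
then clipped to [0, 1.5] (negative reflectance is unphysical; corrected
reflectance can slightly exceed 1). Defaults:

* **Class means μ_c**: the published per-class ρs band averages of the
  4,515-pixel table; the ρt means were never published and default to
  ρs + 0.02, an explicit additive stand-in for the atmospheric path
  contribution.
* **Band correlation ρ = 0.5.**
* **Noise scale s = 0.032** per band. The covariance is
  s²[(1−ρ)I + ρJ], so the optimal accuracy of the equal-prior mixture
  is Φ(d/2) with d the Mahalanobis distance between the class means;
  s is calibrated so this Bayes accuracy is 0.9016, mid-way in the
  0.85–0.95 band that matches the reported accuracy regime of the
  study's classifiers. (At s = 0.02 the same structure would give a
  ceiling of 0.98, out of regime.)

`bayes_accuracy` ignores the physical clipping; at the default
conditions the clipped tail is a fraction of a percent of draws in the
darkest band and the Monte-Carlo agreement test bounds the resulting
bias below 0.005.

What the generator does **not** emulate: skewness and heavy tails of
real reflectance distributions (its class FAI medians equal the means,
unlike the study table's), spatial adjacency and coastline geometry,
cloud contamination, temporal autocorrelation, and any nonlinear class
boundary. The last point matters for interpretation: the mixture's
optimal rule is linear, so on synthetic data all three architectures
converge toward the same ceiling and their relative ordering is seed
noise. Passing tests therefore demonstrate that the pipeline trains,
evaluates and reproduces correctly and that accuracies respect the
analytic ceiling — not that ERISNet beats its baselines on real pixels.

## Problem sizes

The published protocol (3,000 epochs, 4,515 pixels, five-fold ERISNet
cross-validation) is implemented in full generality; the default test
and acceptance runs use reduced sizes chosen as the smallest at which
the statistical checks are meaningful: 150 pixels per class and 40
epochs for the accuracy-regime runs (binomial 3·SE ≈ 2–5 pp around the
0.90 ceiling), 20,000 pixels per class for law-of-large-numbers checks
on the generator, 100,000 draws for the Monte-Carlo check of the Bayes
formula, and 60 pixels per class for perfect-separability runs. Any
larger run is available through the same interfaces.

## Known limitations

* The study's actual pixel table is not distributed with the package;
  fidelity checks against its printed statistics run on generator
  output anchored to those statistics (the per-class FAI *means* follow
  exactly from the band means because FAI is linear in the bands; its
  quantiles do not).
* LSTM recurrent kernels use Glorot-uniform rather than orthogonal
  initialization; with length-14 sequences no stability difference was
  observed.
* Quartiles use linear interpolation between order statistics and the
  standard deviation the n−1 denominator; both conventions are stated
  because the reference statistics do not name theirs.
* Training is single-threaded CPU numpy; the full 3,000-epoch protocol
  on 4,515 pixels is hours of compute, which is why reduced sizes are
  the default.
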