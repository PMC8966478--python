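# Methods

`neurocf` implements counterfactual explanation of a task classifier of 2D
brain-activation maps via multi-domain adversarial image translation, plus
the evaluation protocols that quantify how faithful and robust those
explanations are. This note records the model, the numerical conventions,
and the design choices made where more than one reasonable reading existed.

## Data model and synthetic study conditions

An activation map is an H × W grid of intensities in [0, 1] on a fixed
brain mask; out-of-mask pixels are exactly zero. The real-world analog is a
flattened cortical z-map for one subject and one task contrast, grayscale
and downsampled. Because those maps require a restricted-access download
and heavy preprocessing, the package ships a first-class synthetic
generator emulating their structure:

- a fixed smooth **background** pattern (three broad Gaussians, peak
  amplitude `background_amplitude = 0.35`) shared by all classes — common
  anatomy/vasculature structure;
- per class, `blobs_per_class = 3` localized Gaussian **activation blobs**
  (sd `blob_width = 3` px, amplitude `class_amplitude = 0.5`) at
  class-specific centers, placed greedily so centers of different classes
  stay separated (2.5 × blob width, relaxed only if the packing jams on a
  small mask);
- **per-subject variability**: multiplicative amplitude jitter
  (sd `2.5 × noise_sd`), blob-center jitter (sd `12 × noise_sd` px), and
  i.i.d. pixel noise (sd `noise_sd`). All three scale with one noise dial,
  so `noise_sd = 0` is an exactly deterministic limit.

Each map is clipped and then min-max normalized within the mask, so stored
maps span [0, 1] exactly; this makes the renormalization steps of the
evaluation protocols exact identities at the sweep endpoints (see below).

The default study conditions are seven classes of 32 × 64 maps, 40 per
class, 25% held out stratified by class, `noise_sd = 0.18`. The noise
default was chosen once so the task classifier lands in a realistic,
slightly imperfect regime (high-90s held-out accuracy with a few
misclassified maps), mirroring a real task-decoding CNN that is accurate
but not perfect; a perfect classifier would leave the
misclassification-explanation protocol without cases. The default mask is
two side-by-side ellipses with a midline gap, emulating the two flattened
cortical sheets; it is configurable.

What the generator does **not** emulate: spatially correlated noise,
between-class correlation of activation topographies, hemispheric symmetry,
site/subject covariates, and any neuroanatomical layout. Passing tests
therefore show that the machinery is correct and that the pipeline behaves
as the protocols predict on data with localized class structure — not that
explanations on real fMRI maps would be neurobiologically meaningful.

## Task classifier

A small CNN: five convolution layers (3 × 3, stride 2, ReLU; 8–32
channels) and two fully connected layers ending in a K-way softmax, single
grayscale input channel. Training is SGD on categorical crossentropy,
batch size 10, 50 epochs, with optional stratified k-fold crossvalidation
reporting (folds are disjoint, exhaustive and label-stratified; the
returned model is then trained on the full training split). The final
layer is initialized at 1% scale so an untrained classifier outputs
near-uniform probabilities (crossentropy ≈ ln K).

The default learning rate is 0.05. A rate of 1e-4 is appropriate when
fine-tuning a pretrained backbone, but training this architecture from
scratch at 1e-4 leaves it at chance after 50 epochs; 0.05 trains it to
convergence on the synthetic task in a few seconds. Both are plain config
fields. Argmax ties resolve to the lowest class index, for determinism.

## Counterfactual generator and critic

The generator G(x, c) is a StarGAN-style conditional translator: the
target class enters as K constant one-hot channels concatenated to the
image; three convolutions downsample (strides 1, 2, 2), two stride-1
convolutions form the bottleneck (plain convolutions instead of residual
blocks), and four layers upsample (two stride-2 transposed convolutions,
then two stride-1 convolutions). Instance normalization and ReLU are used
in the generator only. The final activation is a sigmoid — the data
convention here is [0, 1], so a tanh targeting [−1, 1] would be wrong —
and the output is multiplied by the brain mask before any loss, keeping
out-of-mask pixels at zero. Inputs are zero-padded to the next multiple of
4 internally and cropped back, so 50 × 140 or 32 × 64 inputs survive the
two stride-2 stages cleanly.

The discriminator is an unnormalized leaky-ReLU strided conv stack with
two heads: a PatchGAN-style realness head (mean of a patch-score map; an
unbounded Wasserstein critic score) and a domain head (global average
pooling, linear, softmax over K classes). The discriminator is not
conditioned on labels beyond the domain head.

## Training objective

With D_src the critic score, D_cls the domain head, and f the frozen task
classifier:

- `Lwass = E[D_src(x)] − E[D_src(G(x, c))]`, the critic gap;
- `Lgp = E[(‖∇_x̂ D_src(x̂)‖₂ − 1)²]`, x̂ uniform on real–fake segments;
- `Lcls_r = E[−log D_cls(c′ | x)]` on real maps with true labels c′;
- `Lcls_f = E[−log D_cls(c | G(x, c))]` on generated maps with targets c;
- `Lrec = E[‖x − G(G(x, c), c′)‖₁]`, cycle consistency, averaged per
  within-mask pixel (the mean convention keeps λ_rec = 10 scale-appropriate
  regardless of image size; a sum reading would make the weight
  resolution-dependent);
- `Lcnn = E[−log f(c | G(x, c))]`, the frozen-classifier guidance term that
  aligns translations with the decisions being explained.

The discriminator minimizes `−Lwass + λ_gp·Lgp + λ_cls·Lcls_r` (the
standard WGAN-GP critic sign convention: push real scores up, fake scores
down) and the generator minimizes
`−E[D_src(G(x, c))] + λ_cls·Lcls_f + λ_rec·Lrec + λ_cnn·Lcnn`. Defaults:
λ_gp = 10, λ_cls = 1, λ_rec = 10, λ_cnn = 1; Adam with β₁ = 0.5,
β₂ = 0.999, lr = 1e-4, batch 16; five critic updates per generator update.
Target classes for fake batches are drawn uniformly over all K classes,
including the source class. A probability floor of 1e-12 precedes every
logarithm. One integer seed controls initialization, batch order, target
sampling and the interpolation coefficients. With λ_cnn = 0 and K = 2 the
trainer reduces to a plain two-domain StarGAN objective (the Lcnn value is
still computed and reported, just unweighted).

Desk-scale default is 400 generator updates (≈2000 critic updates), which
is enough on the synthetic conditions for ≥90% of held-out counterfactuals
to be assigned their target class; the loop is steps-based rather than
epoch-based so scale is a single number. A non-finite loss halts training
and returns the last good networks.

### Autodiff engine

No deep-learning framework is a dependency; the package carries a compact
reverse-mode autodiff core (`neurocf.nn`) over numpy arrays, sized for
small masked-image networks. Its distinguishing requirement is
double-backward: the gradient penalty contains the norm of an *input*
gradient, and optimizing it differentiates through that gradient with
respect to the critic's parameters. Every vector-Jacobian product is
therefore expressed in the engine's own tensor operations, so gradients
are themselves differentiable. Convolutions are built on an
im2col/col2im adjoint pair of linear primitives, which makes their
higher-order derivatives exact. Gradient correctness is pinned by central
finite-difference checks in float64 (≤1e-5 relative) and a closed-form
double-backward test. Networks run in float32; seeded runs are
bit-reproducible on one platform (bit-identity across BLAS builds is not
guaranteed).

## Explanation protocols

A counterfactual explanation is `CE = counterfactual − original`,
pixelwise, zero off-mask. The stored counterfactual is recomposed as
`original + CE` so the additive identity holds bit-exactly under floating
point.

**Perturbation sweep.** For α in {0, 20, …, 100}: within-mask CE pixels
whose ranking statistic lies strictly below the α-th percentile of that
statistic are zeroed (CE_α); `normalize(original + CE_α)` is classified;
the number of cases assigned the transformation target is counted. The
default ranking statistic is |CE| (perturbing the smallest-magnitude
components first, the robustness reading); signed ranking is available via
a flag and logged per run. Percentiles use linear interpolation between
order statistics, over within-mask pixels only. α = 0 leaves CE unchanged
and α = 100 is special-cased to a fully zeroed CE, so the reconstructions
at the endpoints are exactly the counterfactual and the original (a strict
percentile rule at α = 100 would leave the maximum pixel standing, which
contradicts the endpoint identity the protocol is defined by). Correct
cases get a uniformly random incorrect target class each (seeded);
misclassified cases are targeted at their true class, so at α = 100 the
target-class count is 0 by construction under both protocols.

**Class-mean control.** ΔAve = mean(target-class maps) − mean(source-class
maps), masked; `normalize(original + κ·ΔAve)` is classified for κ on the
grid {0.0, 0.1, …, 5.0} and κ* maximizes the count of target assignments,
ties to the smallest κ. One κ is chosen per (source, target) class pair —
reading "each control explanation" as each ΔAve map — with a per-case mode
available as the alternative reading.

## Counterfactual exaggeration

A map is re-translated toward one class up to 8 times; the texture-like
feature is `x₈ − x₃` (both iteration indices configurable). The feature is
added to every validation map with **no renormalization** (the injection
protocol differs from the sweep in this respect); sums are clipped to
[0, 1] to respect the classifier's input range, and clipping is the logged
convention. The battery extracts 12 features from randomly chosen maps
(target drawn uniformly from the classes other than the source map's own),
measures the fraction of validation maps assigned each feature's class,
and tests the fractions against chance 1/K with an exact two-sided
one-sample Wilcoxon signed-rank test (zero differences dropped before
ranking; exact null enumeration is feasible for n ≤ 20 and the suite
cross-checks the implementation against a direct enumeration oracle).
Fewer than 5 features is refused as underpowered.

## Problem sizes and runtimes

The package's default experiment — 280 maps, 50 classifier epochs, 400
generator updates, full sweep/control/battery evaluation — completes in
roughly 15 minutes on one CPU core. These sizes are the package's
desk-scale defaults; all of them are single config fields and scale up
trivially.

## Known limitations

- The generator and critic are small; at these sizes the adversarial terms
  mainly regularize while the domain and classifier-guidance terms drive
  the translation. Visual realism of counterfactuals is not evaluated.
- **The exaggeration battery does not beat chance at desk scale.** With the
  classifier-guidance weight at its default, one translation already
  saturates the classifier (target probability ≈ 1 at iteration 1), so
  iterations 3–8 wander inside the target-class region and the x₈ − x₃
  feature is class-neutral: injected-feature fractions sit at chance
  (the acceptance suite measures ≈13.8%, p ≈ 0.38, against the 14.3%
  chance level). Feature windows anchored at the original map (e.g.
  x₈ − x₀) do bias the classifier (mean ≈ 27%), and a constructed
  class-mean feature flips >90% of maps, so the injection and rank-test
  machinery is sound; what is missing at this scale is the texture-like
  adversarial vulnerability that a large pretrained CNN on real cortical
  maps exhibits and a small from-scratch CNN on smooth synthetic blobs
  does not. Training the generator less (so iterates converge more slowly)
  lowers the single-step counterfactual success rate below its own
  requirement before it opens an amplification window; the defaults
  therefore keep the documented protocol (window (3, 8), both indices
  configurable) and the suite reports the null result honestly.
- The α = 100 endpoint identity relies on stored maps spanning [0, 1]
  within the mask; datasets not normalized this way make the endpoint
  renormalization a non-identity (the protocol still runs).
- Whether the original protocols ranked CE pixels by signed value or
  magnitude, and whether their normalization was mask-restricted, is not
  determinable from the source material; both choices are explicit here
  (absolute ranking, mask-restricted normalization) with the alternatives
  implemented.
- The exact signed-rank test assumes exchangeable signs under the null;
  injection fractions from one shared validation set are not strictly
  independent across features, as in the original protocol.
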