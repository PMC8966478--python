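# neurocf

Counterfactual explanation of CNN classifiers of brain-activation maps,
via multi-domain adversarial image-to-image translation.

## The problem

Convolutional networks decode which behavioral task produced a cortical
activation map with high accuracy, but they are black boxes: it is hard to
say *which* activation patterns drove a given (correct or incorrect)
decision. A counterfactual explanation answers this directly: minimally
transform the real map so the classifier assigns a different, specified
class, then inspect the difference. Regions with positive/negative
difference are the patterns that push the decision toward/away from the
target class.

`neurocf` is for researchers who want to run this protocol end to end on
masked 2D activation maps (e.g., flattened cortical task-contrast z-maps,
treated as grayscale images) or on the package's synthetic analog of such
data, which ships as a first-class, seeded generator so the whole pipeline
is testable on a desktop without any data download.

## The method

Three models interact:

1. **Task classifier** `f`: a small CNN (five conv layers, two fully
   connected) mapping a masked map to K task probabilities; trained with
   SGD on categorical crossentropy, optionally with stratified k-fold
   crossvalidation. This is the black box being explained; it stays frozen
   afterwards.
2. **Conditional generator** `G(x, c)`: a StarGAN-style translator taking
   a map plus a tiled one-hot target class and emitting a counterfactual
   map in [0, 1] on the same mask.
3. **Critic** `D`: a WGAN-GP discriminator with a realness head `D_src`
   and a domain-classification head `D_cls`.

Training minimizes

    L_D = −(E[D_src(x)] − E[D_src(G(x,c))]) + λ_gp·L_gp + λ_cls·L_cls_real
    L_G = −E[D_src(G(x,c))] + λ_cls·L_cls_fake + λ_rec·L_rec + λ_cnn·L_cnn

with the unit-gradient-norm penalty `L_gp`, cycle-consistency L1
`L_rec = E‖x − G(G(x,c), c′)‖₁`, and — the ingredient that makes the
translator an *explainer* — the frozen-classifier guidance
`L_cnn = E[−log f(c | G(x,c))]`. Defaults: λ_gp = 10, λ_cls = 1,
λ_rec = 10, λ_cnn = 1, Adam(β₁=0.5, β₂=0.999, lr=1e-4), batch 16, five
critic steps per generator step.

The evaluation protocols implemented on top:

- **CE maps** `CE = counterfactual − original` for correctly classified
  maps (toward a random incorrect class) and misclassified maps (toward
  the true class);
- **perturbation sweep**: zero the CE pixels below the α-th percentile of
  |CE|, add back, renormalize, classify, for α ∈ {0, 20, …, 100};
- **class-mean control**: replace CE by κ·ΔAve (difference of class-mean
  maps), κ tuned on {0, 0.1, …, 5};
- **counterfactual exaggeration**: iterate the translation 8 times,
  extract the texture-like feature x₈ − x₃, inject it into validation
  maps, and test the induced target-class fraction against chance 1/K
  with an exact Wilcoxon signed-rank test.

No deep-learning framework is required: the package includes a compact
numpy autodiff engine with the double-backward support the gradient
penalty needs. See `docs/methods.md` for conventions and design choices.

## Worked example

```python
from neurocf.pipeline import run_study

study = run_study(seed=2, verbose=True)
```

prints (seven synthetic classes, 32 × 64 maps, 40 per class, 25% held out):

    dataset: 280 maps, 210 train / 70 val
    classifier held-out accuracy: 0.986
    CAG trained for 400 generator steps
    counterfactuals assigned their target class: 97.6%
    correct-case sweep counts: [64, 64, 63, 51, 29, 0] of 69
    incorrect-case sweep counts: [1, 1, 1, 1, 1, 0] of 1
    battery mean fraction 13.8% (p = 3.75e-01)

Reading: the classifier is accurate but imperfect (1 held-out error);
after adversarial training, 97.6% of held-out maps translated toward a
target class are indeed assigned that target. Zeroing progressively more
of each explanation (α from 0 to 100%) degrades the count of cases
reclassified to the target from 64/69 to, necessarily, 0 — the α = 100
reconstruction is exactly the original map, which by construction is not
assigned the target under either protocol. The misclassified map is
corrected by its counterfactual at α = 0. The exaggeration battery is the
one protocol whose headline effect does not transfer to this desk-scale
setting: at these sizes a single translation already saturates the
classifier, so the x₈ − x₃ feature carries no class signal and the
injected-feature fractions stay at the 14.3% chance level (see
`docs/methods.md`, Known limitations).

The same stages are available as CLI commands over one YAML config
(`neurocf synth`, `train-classifier`, `train-cag`, `explain`, `sweep`,
`exaggerate`), each writing CSV/PNG/JSON artifacts and a reproducibility
manifest into the config's output directory.

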