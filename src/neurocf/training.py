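"""Adversarial training of the counterfactual generator.

The generator is trained against (i) a WGAN-GP critic with an auxiliary
domain-classification head and (ii) a frozen task classifier, with the
objectives

    L_D = -(Lwass_r - Lwass_f) + lambda_gp * Lgp + lambda_cls * Lcls_real
    L_G = -E[D_src(G(x, c))] + lambda_cls * Lcls_fake
          + lambda_rec * Lrec + lambda_cnn * Lcnn

where Lwass = E_x[D_src(x)] - E_{x,c}[D_src(G(x, c))] (the critic maximizes
this gap, written above as minimizing its negative), Lgp is the unit
gradient-norm penalty on real/fake interpolates, Lcls_* are crossentropies
of the critic's domain head, Lrec is the cycle-consistency L1 (mean per
within-mask pixel) and Lcnn is the crossentropy of the frozen classifier on
generated maps against their target class.  Defaults: lambda_gp = 10,
lambda_cls = 1, lambda_rec = 10, lambda_cnn = 1; Adam with beta1 = 0.5,
beta2 = 0.999, lr = 1e-4, batch 16, five critic steps per generator step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import nn
from .classifier import TaskClassifier
from .data import LabeledDataset
from .gan import Discriminator, GanConfig, Generator

__all__ = [
    "LossWeights",
    "CagTrainConfig",
    "TrainState",
    "wasserstein_terms",
    "gradient_penalty",
    "domain_loss_real",
    "domain_loss_fake",
    "reconstruction_loss",
    "classifier_guidance_loss",
    "discriminator_step",
    "generator_step",
    "train_cag",
    "save_loss_history_csv",
]

_EPS = 1e-12  # probability floor before logarithms


@dataclass
class LossWeights:
    lambda_gp: float = 10.0
    lambda_cls: float = 1.0
    lambda_rec: float = 10.0
    lambda_cnn: float = 1.0

    def __post_init__(self):
        if min(self.lambda_gp, self.lambda_cls, self.lambda_rec, self.lambda_cnn) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class CagTrainConfig:
    batch_size: int = 16
    lr: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    gen_steps: int = 400           # desk-scale loop length (generator updates)
    epochs: Optional[int] = None   # if set, overrides gen_steps as full passes
    critic_steps_per_gen_step: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.gen_steps) < 1 or self.lr <= 0:
            raise ValueError("batch_size, gen_steps and lr must be positive")
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be positive when given")


def _to_tensor(batch) -> nn.Tensor:
    if isinstance(batch, nn.Tensor):
        return batch
    arr = np.asarray(batch)
    if arr.ndim == 3:
        arr = arr[:, None]
    return nn.Tensor(arr)


def _scores(disc, x: nn.Tensor) -> nn.Tensor:
    out = disc(x)
    return out[0] if isinstance(out, tuple) else out


def _floored_nll(logp: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Mean -log(p[label]) with an epsilon floor on the probability."""
    p = logp.exp()
    picked = p[np.arange(p.shape[0]), np.asarray(labels)]
    return -((picked + _EPS).log().mean())


# -- loss terms ------------------------------------------------------------

def wasserstein_terms(disc, real_batch, fake_batch):
    """(Lwass_r, Lwass_f, Lwass): mean critic scores and their gap."""
    real = _to_tensor(real_batch)
    fake = _to_tensor(fake_batch)
    if real.shape[0] == 0 or fake.shape[0] == 0:
        raise ValueError("empty batch")
    lw_r = _scores(disc, real).mean()
    lw_f = _scores(disc, fake).mean()
    return lw_r, lw_f, lw_r - lw_f


def gradient_penalty(disc, real_batch, fake_batch, rng: np.random.Generator) -> nn.Tensor:
    """Mean squared deviation of the critic's input-gradient norm from 1.

    Evaluated at per-pair points sampled uniformly on the segment between a
    real and a generated map.
    """
    real = _to_tensor(real_batch)
    fake = _to_tensor(fake_batch)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share shape")
    n = real.shape[0]
    t = rng.uniform(size=(n,) + (1,) * (real.ndim - 1)).astype(real.dtype)
    xhat = nn.Tensor(t * real.data + (1.0 - t) * fake.data, requires_grad=True)
    score_sum = _scores(disc, xhat).sum()
    (g,) = nn.grad(score_sum, [xhat], create_graph=True)
    axes = tuple(range(1, real.ndim))
    norms = (g * g).sum(axis=axes).sqrt()
    return ((norms - 1.0) ** 2).mean()


def domain_loss_real(disc, real_batch, labels) -> nn.Tensor:
    """Crossentropy of the domain head on real maps against true labels."""
    _, domain_logp = disc(_to_tensor(real_batch))
    return _floored_nll(domain_logp, labels)


def domain_loss_fake(disc, gen, real_batch, target_labels) -> nn.Tensor:
    """Crossentropy of the domain head on generated maps against targets."""
    fake = gen(_to_tensor(real_batch), np.asarray(target_labels))
    _, domain_logp = disc(fake)
    return _floored_nll(domain_logp, target_labels)


def reconstruction_loss(gen, real_batch, target_labels, original_labels) -> nn.Tensor:
    """Cycle-consistency L1 between x and G(G(x, c), c'), averaged per pixel.

    With masked generators both maps vanish off-mask, so the per-within-mask
    -pixel average equals the all-pixel sum divided by (batch * mask size).
    """
    real = _to_tensor(real_batch)
    fake = gen(real, np.asarray(target_labels))
    recon = gen(fake, np.asarray(original_labels))
    diff = (real - recon).abs()
    mask = getattr(gen, "mask", None)
    denom = int(mask.sum()) if mask is not None else int(np.prod(real.shape[1:]))
    return diff.sum() * (1.0 / (real.shape[0] * denom))


def classifier_guidance_loss(clf, fake_batch, target_labels) -> nn.Tensor:
    """Crossentropy of the frozen classifier on generated maps vs targets."""
    fake = _to_tensor(fake_batch)
    logp = clf.log_probs(fake) if hasattr(clf, "log_probs") else clf(fake)
    return _floored_nll(logp, target_labels)


# -- optimization steps ----------------------------------------------------

class TrainState:
    """Bundles the three networks, their optimizers and the training RNG."""

    def __init__(self, gen: Generator, disc: Discriminator, clf: TaskClassifier,
                 weights: LossWeights, cfg: CagTrainConfig):
        self.gen, self.disc, self.clf = gen, disc, clf
        self.weights, self.cfg = weights, cfg
        self.opt_g = nn.Adam(gen.parameters(), lr=cfg.lr,
                             beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self.opt_d = nn.Adam(disc.parameters(), lr=cfg.lr,
                             beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self.rng = np.random.default_rng(cfg.seed)
        for p in clf.parameters():  # the explanation target stays frozen
            p.requires_grad = False

    def sample_targets(self, n: int) -> np.ndarray:
        return self.rng.integers(0, self.gen.cfg.K, size=n)


class _frozen:
    """Temporarily drop requires_grad on a module's parameters."""

    def __init__(self, *modules):
        self.params = [p for m in modules for p in m.parameters()]

    def __enter__(self):
        self.saved = [p.requires_grad for p in self.params]
        for p in self.params:
            p.requires_grad = False

    def __exit__(self, *exc):
        for p, s in zip(self.params, self.saved):
            p.requires_grad = s
        return False


def discriminator_step(state: TrainState, real_batch, labels) -> dict:
    """One Adam update of the critic; generator and classifier untouched."""
    real = _to_tensor(real_batch)
    targets = state.sample_targets(real.shape[0])
    with nn.no_grad():
        fake = state.gen(real, targets).detach()
    with _frozen(state.gen):
        lw_r, lw_f, lwass = wasserstein_terms(state.disc, real, fake)
        lgp = gradient_penalty(state.disc, real, fake, state.rng)
        lcls_r = domain_loss_real(state.disc, real, labels)
        w = state.weights
        ld = -lwass + w.lambda_gp * lgp + w.lambda_cls * lcls_r
        report = {
            "Lwass_r": lw_r.item(), "Lwass_f": lw_f.item(), "Lwass": lwass.item(),
            "Lgp": lgp.item(), "Lcls_r": lcls_r.item(), "LD": ld.item(),
        }
        if not np.isfinite(ld.item()):
            raise FloatingPointError(f"non-finite discriminator loss: {report}")
        state.opt_d.zero_grad()
        ld.backward()
        state.opt_d.step()
    return report


def generator_step(state: TrainState, real_batch, labels) -> dict:
    """One Adam update of the generator; critic and classifier untouched."""
    real = _to_tensor(real_batch)
    labels = np.asarray(labels)
    targets = state.sample_targets(real.shape[0])
    w = state.weights
    with _frozen(state.disc, state.clf):
        fake = state.gen(real, targets)
        score_f, domain_logp = state.disc(fake)
        lw_f = score_f.mean()
        lcls_f = _floored_nll(domain_logp, targets)
        recon = state.gen(fake, labels)
        mask_n = int(state.gen.mask.sum())
        lrec = (real - recon).abs().sum() * (1.0 / (real.shape[0] * mask_n))
        lcnn = classifier_guidance_loss(state.clf, fake, targets)
        lg = -lw_f + w.lambda_cls * lcls_f + w.lambda_rec * lrec + w.lambda_cnn * lcnn
        with nn.no_grad():
            lw_r = _scores(state.disc, real).mean().item()
        report = {
            "Lwass_r": lw_r, "Lwass_f": lw_f.item(), "Lwass": lw_r - lw_f.item(),
            "Lcls_f": lcls_f.item(), "Lrec": lrec.item(), "Lcnn": lcnn.item(),
            "LG": lg.item(),
        }
        if not np.isfinite(lg.item()):
            raise FloatingPointError(f"non-finite generator loss: {report}")
        state.opt_g.zero_grad()
        lg.backward()
        state.opt_g.step()
    return report


def train_cag(
    clf: TaskClassifier,
    ds: LabeledDataset,
    weights: Optional[LossWeights] = None,
    cfg: Optional[CagTrainConfig] = None,
    gan_cfg: Optional[GanConfig] = None,
    callback: Optional[Callable[[int, dict], None]] = None,
) -> tuple[Generator, Discriminator, list[dict]]:
    """Alternating WGAN-GP training of the generator against the frozen classifier.

    Runs ``critic_steps_per_gen_step`` critic updates per generator update,
    sampling batches (and target classes, uniformly over all K) from one
    seeded RNG.  A non-finite loss halts training, returning the last good
    networks and history.
    """
    if len(ds) == 0:
        raise ValueError("cannot train on an empty dataset")
    if weights is None:
        weights = LossWeights()
    if cfg is None:
        cfg = CagTrainConfig()
    if gan_cfg is None:
        gan_cfg = GanConfig(input_shape=ds.maps[0].shape, K=ds.n_classes,
                            seed=cfg.seed)
    gen = Generator(gan_cfg, ds.mask)
    disc = Discriminator(gan_cfg)
    state = TrainState(gen, disc, clf, weights, cfg)

    x_all = ds.values_array()[:, None].astype(np.float32)
    y_all = ds.labels_array()
    n = len(ds)
    bs = min(cfg.batch_size, n)
    if cfg.epochs is not None:
        total_steps = cfg.epochs * max(1, n // bs)
    else:
        total_steps = cfg.gen_steps

    def draw():
        idx = state.rng.choice(n, size=bs, replace=n < bs)
        return x_all[idx], y_all[idx]

    history: list[dict] = []
    for step in range(total_steps):
        try:
            for _ in range(cfg.critic_steps_per_gen_step):
                xb, yb = draw()
                d_report = discriminator_step(state, xb, yb)
            xb, yb = draw()
            g_report = generator_step(state, xb, yb)
        except FloatingPointError:
            break  # divergence: keep last good networks and history
        row = {"step": step, **{f"D_{k}": v for k, v in d_report.items()},
               **{f"G_{k}": v for k, v in g_report.items()}}
        history.append(row)
        if callback is not None:
            callback(step, row)
    return gen, disc, history


def save_loss_history_csv(history: list[dict], path) -> None:
    if not history:
        return
    keys = list(history[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)
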