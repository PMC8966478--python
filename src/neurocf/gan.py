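"""Multi-domain conditional generator and discriminator for activation maps.

The generator follows the StarGAN layout adapted to small masked grayscale
images: the target class enters as K constant one-hot channels tiled to the
image size and concatenated to the map; three convolution layers downsample
(strides 1, 2, 2), two stride-1 convolutions form the bottleneck (residual
blocks are deliberately replaced by plain convolutions), and four layers
upsample back (two stride-2 transposed convolutions, then two stride-1
convolutions).  Instance normalization is used in the generator only.  The
final sigmoid keeps outputs in [0, 1] — the data convention here — and the
brain mask multiplies the output, so out-of-mask pixels are exactly zero.

The discriminator is an unnormalized leaky-ReLU strided conv stack with two
heads: an unbounded realness score (mean of a patch-score map, the WGAN
critic) and a K-way domain classification head (global average pooling,
linear, softmax).

Inputs of arbitrary size are zero-padded internally to the next multiple of
4 so the two stride-2 stages divide cleanly, and cropped back on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .data import ActivationMap

__all__ = [
    "GanConfig",
    "Generator",
    "Discriminator",
    "condition_input",
    "condition_batch",
    "generate_counterfactual",
    "discriminate",
    "save_gan_model",
    "load_generator",
    "load_discriminator",
]


@dataclass
class GanConfig:
    input_shape: tuple[int, int] = (32, 64)
    K: int = 7
    base_channels: int = 8
    leaky_slope: float = 0.01
    seed: int = 0


def _pad_to_multiple(x: nn.Tensor, multiple: int = 4) -> tuple[nn.Tensor, tuple[int, int]]:
    n, c, h, w = x.shape
    hp = -(-h // multiple) * multiple
    wp = -(-w // multiple) * multiple
    if (hp, wp) == (h, w):
        return x, (h, w)
    return (
        x.embed((n, c, hp, wp), (slice(None), slice(None), slice(0, h), slice(0, w))),
        (h, w),
    )


def condition_input(amap: ActivationMap, target: int, K: int) -> np.ndarray:
    """Stack the map with K tiled one-hot label channels -> (K+1, H, W)."""
    if not 0 <= target < K:
        raise ValueError(f"target class {target} outside 0..{K - 1}")
    h, w = amap.shape
    stack = np.zeros((K + 1, h, w))
    stack[0] = amap.values
    stack[1 + target] = 1.0
    return stack


def condition_batch(x: nn.Tensor, targets: np.ndarray, K: int) -> nn.Tensor:
    """Concatenate tiled one-hot target channels to a (N, 1, H, W) batch."""
    targets = np.asarray(targets)
    if targets.min() < 0 or targets.max() >= K:
        raise ValueError("target class out of range")
    n, _, h, w = x.shape
    onehot = np.zeros((n, K, h, w), dtype=np.float32)
    onehot[np.arange(n), targets] = 1.0
    return nn.concat([x, nn.Tensor(onehot)], axis=1)


class Generator(nn.Module):
    """Conditional image translator ``G(x, c) -> x^c``."""

    def __init__(self, cfg: GanConfig, mask: np.ndarray):
        self.cfg = cfg
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != tuple(cfg.input_shape):
            raise ValueError("mask shape must match input_shape")
        rng = np.random.default_rng(cfg.seed)
        c, K = cfg.base_channels, cfg.K
        self.down = nn.Sequential(
            nn.Conv2d(K + 1, c, 7, rng, stride=1, padding=3),
            nn.InstanceNorm2d(c), nn.ReLU(),
            nn.Conv2d(c, 2 * c, 4, rng, stride=2, padding=1),
            nn.InstanceNorm2d(2 * c), nn.ReLU(),
            nn.Conv2d(2 * c, 4 * c, 4, rng, stride=2, padding=1),
            nn.InstanceNorm2d(4 * c), nn.ReLU(),
        )
        self.bottleneck = nn.Sequential(
            nn.Conv2d(4 * c, 4 * c, 3, rng, stride=1, padding=1),
            nn.InstanceNorm2d(4 * c), nn.ReLU(),
            nn.Conv2d(4 * c, 4 * c, 3, rng, stride=1, padding=1),
            nn.InstanceNorm2d(4 * c), nn.ReLU(),
        )
        self.up = nn.Sequential(
            nn.ConvTranspose2d(4 * c, 2 * c, 4, rng, stride=2, padding=1),
            nn.InstanceNorm2d(2 * c), nn.ReLU(),
            nn.ConvTranspose2d(2 * c, c, 4, rng, stride=2, padding=1),
            nn.InstanceNorm2d(c), nn.ReLU(),
            nn.Conv2d(c, c, 3, rng, stride=1, padding=1),
            nn.InstanceNorm2d(c), nn.ReLU(),
            nn.Conv2d(c, 1, 7, rng, stride=1, padding=3),
        )

    def forward(self, x: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
        """Translate a (N, 1, H, W) batch toward per-sample target classes."""
        if x.shape[2:] != tuple(self.cfg.input_shape):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != {self.cfg.input_shape}"
            )
        z = condition_batch(x, targets, self.cfg.K)
        z, (h, w) = _pad_to_multiple(z, 4)
        z = self.up(self.bottleneck(self.down(z)))
        z = z[:, :, :h, :w].sigmoid()
        return z * nn.Tensor(self.mask.astype(np.float32))


class Discriminator(nn.Module):
    """Critic with an unbounded realness head and a K-way domain head."""

    def __init__(self, cfg: GanConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        c = cfg.base_channels
        slope = cfg.leaky_slope
        self.trunk = nn.Sequential(
            nn.Conv2d(1, c, 4, rng, stride=2, padding=1), nn.LeakyReLU(slope),
            nn.Conv2d(c, 2 * c, 4, rng, stride=2, padding=1), nn.LeakyReLU(slope),
            nn.Conv2d(2 * c, 4 * c, 4, rng, stride=2, padding=1), nn.LeakyReLU(slope),
        )
        self.patch_head = nn.Conv2d(4 * c, 1, 3, rng, stride=1, padding=1)
        self.domain_head = nn.Linear(4 * c, cfg.K, rng)

    def patch_scores(self, x: nn.Tensor) -> nn.Tensor:
        z, _ = _pad_to_multiple(x, 8)
        return self.patch_head(self.trunk(z))

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Return (realness score (N,), domain log-probabilities (N, K))."""
        z, _ = _pad_to_multiple(x, 8)
        feat = self.trunk(z)
        score = self.patch_head(feat).mean(axis=(1, 2, 3))
        pooled = feat.mean(axis=(2, 3))
        domain_logp = nn.log_softmax(self.domain_head(pooled), axis=1)
        return score, domain_logp


def generate_counterfactual(gen: Generator, amap: ActivationMap,
                            target: int) -> ActivationMap:
    """Translate one map toward ``target``; output shares the input's mask."""
    if not 0 <= target < gen.cfg.K:
        raise ValueError(f"target class {target} outside 0..{gen.cfg.K - 1}")
    x = nn.Tensor(amap.values[None, None])
    with nn.no_grad():
        out = gen(x, np.array([target])).data[0, 0]
    values = np.where(gen.mask, np.clip(np.asarray(out, dtype=np.float64), 0.0, 1.0), 0.0)
    return ActivationMap(values, amap.mask, label=amap.label,
                         id=f"{amap.id}->t{target}")


def discriminate(disc: Discriminator, amap: ActivationMap) -> tuple[float, np.ndarray]:
    """Realness score and domain probability vector for one map."""
    x = nn.Tensor(amap.values[None, None].astype(np.float32))
    with nn.no_grad():
        score, domain_logp = disc(x)
    return float(score.data[0]), np.exp(domain_logp.data[0]).astype(np.float64)


def save_gan_model(model: nn.Module, path) -> None:
    """Versioned checkpoint: config JSON + mask (generator) + parameters."""
    meta = {"format": 1, "kind": type(model).__name__, "config": asdict(model.cfg)}
    extra = {}
    if isinstance(model, Generator):
        extra["__mask__"] = model.mask
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **extra, **model.state_dict())


def _load(path, expected_kind: str):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["kind"] != expected_kind:
            raise ValueError(f"checkpoint holds a {meta['kind']}, not {expected_kind}")
        cfg_dict = meta["config"]
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        cfg = GanConfig(**cfg_dict)
        state = {k: z[k] for k in z.files if not k.startswith("__")}
        mask = z["__mask__"] if "__mask__" in z.files else None
    if expected_kind == "Generator":
        model = Generator(cfg, mask)
    else:
        model = Discriminator(cfg)
    model.load_state_dict(state)
    return model


def load_generator(path) -> Generator:
    return _load(path, "Generator")


def load_discriminator(path) -> Discriminator:
    return _load(path, "Discriminator")
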