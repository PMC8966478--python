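"""Single-file run configuration and reproducibility manifest.

One YAML file holds every stage's hyperparameters; one global seed
deterministically derives each stage's sub-seed, so a config plus its seed
reproduces every artifact.  Each CLI command appends to a manifest recording
the config snapshot, seed, package version and SHA-256 of its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classifier import ClassifierConfig
from .data import SynthConfig
from .gan import GanConfig
from .training import CagTrainConfig, LossWeights

__all__ = ["EvalConfig", "RunConfig", "load_run_config", "save_run_config",
           "update_manifest"]


@dataclass
class EvalConfig:
    alphas: list[float] = field(default_factory=lambda: [0, 20, 40, 60, 80, 100])
    ranking: str = "absolute"
    n_features: int = 12
    n_exaggeration_iters: int = 8
    feature_early_iter: int = 3
    val_fraction: float = 0.25


@dataclass
class RunConfig:
    outdir: str = "runs/default"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    cag: CagTrainConfig = field(default_factory=CagTrainConfig)
    weights: LossWeights = field(default_factory=LossWeights)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def resolve(self) -> "RunConfig":
        """Propagate the global seed and shapes into every stage config."""
        self.synth.seed = self.seed
        self.classifier.seed = self.seed + 1
        self.gan.seed = self.seed + 2
        self.cag.seed = self.seed + 3
        shape = (self.synth.H, self.synth.W)
        self.classifier.input_shape = shape
        self.classifier.K = self.synth.K
        self.gan.input_shape = shape
        self.gan.K = self.synth.K
        return self

    # derived artifact paths -------------------------------------------------
    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        outdir=raw.get("outdir", "runs/default"),
        seed=int(raw.get("seed", 0)),
        synth=SynthConfig(**raw.get("synth", {})),
        classifier=_classifier_from(raw.get("classifier", {})),
        gan=_gan_from(raw.get("gan", {})),
        cag=CagTrainConfig(**raw.get("cag", {})),
        weights=LossWeights(**raw.get("weights", {})),
        eval=EvalConfig(**raw.get("eval", {})),
    )
    return cfg.resolve()


def _classifier_from(d: dict) -> ClassifierConfig:
    d = dict(d)
    if "input_shape" in d:
        d["input_shape"] = tuple(d["input_shape"])
    if "conv_blocks" in d:
        d["conv_blocks"] = [tuple(b) for b in d["conv_blocks"]]
    return ClassifierConfig(**d)


def _gan_from(d: dict) -> GanConfig:
    d = dict(d)
    if "input_shape" in d:
        d["input_shape"] = tuple(d["input_shape"])
    return GanConfig(**d)


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "outdir": cfg.outdir,
                "seed": cfg.seed,
                "synth": asdict(cfg.synth),
                "classifier": asdict(cfg.classifier),
                "gan": asdict(cfg.gan),
                "cag": asdict(cfg.cag),
                "weights": asdict(cfg.weights),
                "eval": asdict(cfg.eval),
            },
            fh,
            sort_keys=False,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def update_manifest(cfg: RunConfig, command: str, artifacts: list[Path]) -> None:
    """Record a command's config snapshot, seed, version and artifact hashes."""
    manifest_path = cfg.path("manifest.json")
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[command] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps({
            "synth": asdict(cfg.synth), "classifier": asdict(cfg.classifier),
            "gan": asdict(cfg.gan), "cag": asdict(cfg.cag),
            "weights": asdict(cfg.weights), "eval": asdict(cfg.eval),
        })),
        "artifacts": {str(p): _sha256(p) for p in artifacts if Path(p).exists()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
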