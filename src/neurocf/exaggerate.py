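"""Counterfactual exaggeration, feature extraction and the injection test.

Iterating the generator toward one class amplifies subtle class-relevant
image structure.  The texture-like feature is isolated by subtracting the
third iterate from the eighth; injecting that feature into validation maps
and counting how often the classifier assigns the feature's class measures
how strongly the classifier leans on such structure.  A battery of features
extracted from randomly chosen maps is compared against the 1/K chance
level with an exact two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .classifier import TaskClassifier
from .data import ActivationMap, LabeledDataset
from .gan import Generator, generate_counterfactual

__all__ = [
    "ExaggerationTrajectory",
    "ExtractedFeature",
    "BatteryResult",
    "exaggerate",
    "extract_feature",
    "inject_and_evaluate",
    "signed_rank_test",
    "feature_battery",
]


@dataclass
class ExaggerationTrajectory:
    """Maps x_0 ... x_n with x_i = G(x_{i-1}, target)."""

    maps: list[ActivationMap]
    target_class: int

    @property
    def n_iterations(self) -> int:
        return len(self.maps) - 1


@dataclass
class ExtractedFeature:
    """Difference of two iterates (by default x_8 - x_3); zero off-mask."""

    feature: np.ndarray
    target_class: int
    source_id: str
    iterations_used: tuple[int, int]


def exaggerate(gen: Generator, amap: ActivationMap, target: int,
               n: int = 8) -> ExaggerationTrajectory:
    """Iteratively re-translate a map toward ``target`` for ``n`` steps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    maps = [amap]
    current = amap
    for _ in range(n):
        current = generate_counterfactual(gen, current, target)
        maps.append(current)
    return ExaggerationTrajectory(maps, target)


def extract_feature(traj: ExaggerationTrajectory, late: int = 8,
                    early: int = 3) -> ExtractedFeature:
    """feature = x_late - x_early (defaults: eighth minus third iterate)."""
    if traj.n_iterations < late:
        raise ValueError(
            f"trajectory has {traj.n_iterations} iterations, needs >= {late}"
        )
    feature = traj.maps[late].values - traj.maps[early].values
    return ExtractedFeature(feature, traj.target_class, traj.maps[0].id,
                            (early, late))


def inject_and_evaluate(clf: TaskClassifier, feature: ExtractedFeature,
                        ds: LabeledDataset) -> float:
    """Fraction of maps assigned the feature's class after adding the feature.

    No renormalization is applied after the addition; the sum is clipped to
    [0, 1] to respect the classifier's input range (off-mask stays zero).
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    if feature.feature.shape != ds.maps[0].shape:
        raise ValueError("feature and dataset maps differ in shape")
    batch = ds.values_array() + feature.feature[None]
    batch = np.clip(batch, 0.0, 1.0)
    batch[:, ~ds.mask] = 0.0
    pred = clf.predict(batch)
    return float(np.mean(pred == feature.target_class))


def signed_rank_test(fractions: np.ndarray, chance: float) -> float:
    """Exact two-sided one-sample Wilcoxon signed-rank p against ``chance``.

    Differences exactly equal to zero are dropped before ranking.
    """
    diffs = np.asarray(fractions, dtype=float) - chance
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        return 1.0
    res = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided",
                         method="exact")
    return float(res.pvalue)


@dataclass
class BatteryResult:
    fractions: np.ndarray
    targets: list[int]
    source_ids: list[str]
    chance: float
    p_value: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def sd(self) -> float:
        return float(np.std(self.fractions, ddof=1)) if len(self.fractions) > 1 else 0.0

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["feature", "source_id", "target_class", "fraction"])
            for i, (sid, tgt, fr) in enumerate(
                zip(self.source_ids, self.targets, self.fractions)
            ):
                writer.writerow([i, sid, tgt, f"{fr:.6f}"])

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_features": len(self.fractions), "mean": self.mean,
                 "sd": self.sd, "chance": self.chance, "p_value": self.p_value},
                fh, indent=2,
            )


def feature_battery(
    gen: Generator,
    clf: TaskClassifier,
    ds: LabeledDataset,
    n_features: int = 12,
    seed: int = 0,
    n_iterations: int = 8,
    early: int = 3,
    eval_ds: Optional[LabeledDataset] = None,
) -> BatteryResult:
    """Extract features from randomly chosen maps and test against chance.

    Source maps are sampled without replacement; each feature's target class
    is drawn uniformly from the classes other than the source map's own.
    Injection fractions are measured on ``eval_ds`` (default: ``ds`` itself)
    and compared with chance 1/K by the exact signed-rank test.
    """
    if n_features < 5:
        raise ValueError("n_features < 5: too few for a meaningful rank test")
    if eval_ds is None:
        eval_ds = ds
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ds), size=min(n_features, len(ds)),
                     replace=len(ds) < n_features)
    fractions, targets, source_ids = [], [], []
    for i in idx:
        amap = ds.maps[int(i)]
        others = [k for k in range(ds.n_classes) if k != amap.label]
        target = int(rng.choice(others))
        traj = exaggerate(gen, amap, target, n=n_iterations)
        feat = extract_feature(traj, late=n_iterations, early=early)
        fractions.append(inject_and_evaluate(clf, feat, eval_ds))
        targets.append(target)
        source_ids.append(amap.id)
    chance = 1.0 / ds.n_classes
    p = signed_rank_test(np.array(fractions), chance)
    return BatteryResult(np.array(fractions), targets, source_ids, chance, p)
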