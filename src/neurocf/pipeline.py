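"""End-to-end desk-scale study: data -> classifier -> generator -> evaluations.

This is the programmatic equivalent of running every CLI command in order,
at the package's default study conditions (seven classes of 32 x 64 masked
maps, 40 maps per class, 25% held out).  One integer seed determines every
stochastic choice.  Used by the example workflow and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .classifier import (ClassifierConfig, TaskClassifier, build_classifier,
                         evaluate_confusion, train_classifier)
from .data import LabeledDataset, SynthConfig, generate_synthetic_dataset, stratified_split
from .exaggerate import BatteryResult, feature_battery
from .explain import (DEFAULT_ALPHAS, PerturbationSweepResult,
                      explain_misclassification, perturbation_sweep,
                      run_control_analysis, select_correct_cases)
from .gan import Discriminator, GanConfig, Generator
from .training import CagTrainConfig, LossWeights, train_cag

__all__ = ["StudyResult", "run_study", "counterfactual_confusion"]


@dataclass
class StudyResult:
    dataset: LabeledDataset
    train: LabeledDataset
    val: LabeledDataset
    clf: TaskClassifier
    val_accuracy: float
    gen: Generator
    disc: Discriminator
    cag_history: list[dict]
    cf_target_rate: float
    correct_sweep: Optional[PerturbationSweepResult] = None
    incorrect_sweep: Optional[PerturbationSweepResult] = None
    correct_control: Optional[object] = None
    incorrect_control: Optional[object] = None
    battery: Optional[BatteryResult] = None
    extras: dict = field(default_factory=dict)


def counterfactual_confusion(gen: Generator, clf: TaskClassifier,
                             ds: LabeledDataset) -> np.ndarray:
    """counts[c, j]: translating every map toward c, how often clf assigns j."""
    K = gen.cfg.K
    counts = np.zeros((K, K), dtype=np.int64)
    x = nn.Tensor(ds.values_array()[:, None].astype(np.float32))
    for c in range(K):
        with nn.no_grad():
            fake = gen(x, np.full(len(ds), c)).data[:, 0]
        pred = clf.predict(fake.astype(np.float64))
        for j in range(K):
            counts[c, j] = int((pred == j).sum())
    return counts


def run_study(
    seed: int = 0,
    synth: Optional[SynthConfig] = None,
    classifier_cfg: Optional[ClassifierConfig] = None,
    cag_cfg: Optional[CagTrainConfig] = None,
    gan_cfg: Optional[GanConfig] = None,
    weights: Optional[LossWeights] = None,
    val_fraction: float = 0.25,
    with_sweeps: bool = True,
    with_controls: bool = True,
    with_battery: bool = True,
    n_features: int = 12,
    verbose: bool = False,
) -> StudyResult:
    """Run the whole study from one seed and return every measured quantity."""

    def log(msg: str) -> None:
        if verbose:
            print(msg, flush=True)

    synth = synth or SynthConfig(seed=seed)
    synth.seed = seed
    ds = generate_synthetic_dataset(synth)
    train, val = stratified_split(ds, val_fraction, seed=seed + 10)
    log(f"dataset: {len(ds)} maps, {len(train)} train / {len(val)} val")

    ccfg = classifier_cfg or ClassifierConfig()
    ccfg.seed = seed + 1
    ccfg.input_shape = (synth.H, synth.W)
    ccfg.K = synth.K
    clf = build_classifier(ccfg)
    clf, _ = train_classifier(clf, train, ccfg)
    cm = evaluate_confusion(clf, val)
    log(f"classifier held-out accuracy: {cm.accuracy:.3f}")

    cag_cfg = cag_cfg or CagTrainConfig()
    cag_cfg.seed = seed + 3
    gan_cfg = gan_cfg or GanConfig()
    gan_cfg.seed = seed + 2
    gan_cfg.input_shape = (synth.H, synth.W)
    gan_cfg.K = synth.K
    gen, disc, history = train_cag(clf, train, weights or LossWeights(),
                                   cag_cfg, gan_cfg)
    log(f"CAG trained for {len(history)} generator steps")

    cf_counts = counterfactual_confusion(gen, clf, val)
    cf_rate = float(np.trace(cf_counts) / cf_counts.sum())
    log(f"counterfactuals assigned their target class: {100 * cf_rate:.1f}%")

    result = StudyResult(ds, train, val, clf, cm.accuracy, gen, disc, history,
                         cf_rate, extras={"confusion": cm,
                                          "cf_confusion": cf_counts})

    if with_sweeps:
        rng = np.random.default_rng(seed + 21)
        correct_cases = select_correct_cases(clf, val, rng)
        result.correct_sweep, _ = perturbation_sweep(gen, clf, correct_cases,
                                                     DEFAULT_ALPHAS)
        log(f"correct-case sweep counts: {result.correct_sweep.counts} "
            f"of {result.correct_sweep.n_cases}")
        result.incorrect_sweep, _, result.incorrect_control = (
            explain_misclassification(gen, clf, val, DEFAULT_ALPHAS,
                                      with_control=with_controls)
        )
        log(f"incorrect-case sweep counts: {result.incorrect_sweep.counts} "
            f"of {result.incorrect_sweep.n_cases}")
        if with_controls:
            result.correct_control = run_control_analysis(clf, val, correct_cases)

    if with_battery:
        result.battery = feature_battery(gen, clf, val, n_features=n_features,
                                         seed=seed + 22)
        log(f"battery mean fraction {100 * result.battery.mean:.1f}% "
            f"(p = {result.battery.p_value:.2e})")
    return result
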