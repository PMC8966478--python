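"""Counterfactual explanations and their quantitative evaluation protocols.

A counterfactual explanation (CE) is the pixelwise difference between a
generated counterfactual map and the original map.  Two evaluations are
implemented:

* the perturbation sweep — pixels of the CE whose ranking statistic falls
  below the alpha-th within-mask percentile are zeroed (``CE_alpha``), the
  truncated CE is added back to the original, the sum is min-max normalized
  and classified, and the number of cases assigned the transformation target
  is counted for alpha in {0, 20, ..., 100};
* the class-mean control — the difference of class-mean maps (Delta-Ave,
  target mean minus source mean) is added with a gain kappa chosen on the
  grid {0.0, 0.1, ..., 5.0} to maximize the number of cases assigned the
  target class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifier import TaskClassifier
from .data import ActivationMap, LabeledDataset, minmax_normalize
from .gan import Generator, generate_counterfactual

__all__ = [
    "CounterfactualExplanation",
    "PerturbationSweepResult",
    "ControlResult",
    "explain",
    "threshold_ce",
    "perturbation_sweep",
    "control_delta_ave",
    "kappa_search",
    "select_correct_cases",
    "select_misclassified_cases",
    "explain_misclassification",
    "DEFAULT_ALPHAS",
    "KAPPA_GRID",
]

DEFAULT_ALPHAS = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
KAPPA_GRID = tuple(np.round(np.arange(0, 5.01, 0.1), 1))


@dataclass
class CounterfactualExplanation:
    """Original map, its counterfactual, and their exact pixelwise difference."""

    original: ActivationMap
    counterfactual: ActivationMap
    ce: np.ndarray
    source_class: int
    target_class: int

    def __post_init__(self):
        if self.source_class == self.target_class:
            raise ValueError("source and target class must differ")


@dataclass
class PerturbationSweepResult:
    alphas: list[float]
    counts: list[int]
    n_cases: int

    def percents(self) -> list[float]:
        if self.n_cases == 0:
            return [0.0 for _ in self.counts]
        return [100.0 * c / self.n_cases for c in self.counts]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["alpha", "count", "percent"])
            for a, c, p in zip(self.alphas, self.counts, self.percents()):
                writer.writerow([a, c, f"{p:.1f}"])


@dataclass
class ControlResult:
    """Per class pair: the Delta-Ave map, chosen kappa, and target-class count."""

    pair_results: dict = field(default_factory=dict)
    n_cases: int = 0
    total_count: int = 0

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "kappa", "count", "n_pair"])
            for (src, tgt), rec in sorted(self.pair_results.items()):
                writer.writerow([src, tgt, rec["kappa"], rec["count"], rec["n_pair"]])


def explain(gen: Generator, clf: TaskClassifier, amap: ActivationMap,
            target: int, source: Optional[int] = None) -> CounterfactualExplanation:
    """Translate ``amap`` toward ``target`` and form the CE difference map.

    ``source`` defaults to the classifier's assigned class; passing the true
    label instead is the caller's (recorded) choice.
    """
    if source is None:
        source = int(clf.predict(amap)[0])
    if target == source:
        raise ValueError("target class must differ from source class")
    counterfactual = generate_counterfactual(gen, amap, target)
    ce = counterfactual.values - amap.values
    # recompose so original + ce == counterfactual holds bit-exactly
    counterfactual = ActivationMap(amap.values + ce, amap.mask,
                                   label=counterfactual.label,
                                   id=counterfactual.id)
    return CounterfactualExplanation(amap, counterfactual, ce, source, target)


def threshold_ce(ce: np.ndarray, alpha: float, mask: np.ndarray,
                 ranking: str = "absolute") -> np.ndarray:
    """Zero within-mask CE pixels ranking strictly below the alpha-th percentile.

    ``ranking='absolute'`` ranks by |CE| (small-magnitude components are
    perturbed first); ``'signed'`` ranks by the signed value.  alpha = 0
    returns the CE unchanged and alpha = 100 a fully zeroed grid, so the
    reconstructions at the sweep's ends are exactly the counterfactual and
    the original.
    """
    if not 0.0 <= alpha <= 100.0:
        raise ValueError("alpha must lie in [0, 100]")
    if ranking not in ("absolute", "signed"):
        raise ValueError("ranking must be 'absolute' or 'signed'")
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, ce, 0.0)
    if alpha == 0.0:
        return out
    if alpha == 100.0:
        return np.zeros_like(out)
    stat = np.abs(ce) if ranking == "absolute" else ce
    cut = np.percentile(stat[mask], alpha)  # linear-interpolation convention
    out[(stat < cut) | ~mask] = 0.0
    return out


def select_correct_cases(clf: TaskClassifier, ds: LabeledDataset,
                         rng: np.random.Generator) -> list[tuple[ActivationMap, int]]:
    """Correctly classified maps, each with a random incorrect target class."""
    pred = clf.predict(ds)
    labels = ds.labels_array()
    cases = []
    for m, p, y in zip(ds.maps, pred, labels):
        if p == y:
            others = [k for k in range(ds.n_classes) if k != y]
            cases.append((m, int(rng.choice(others))))
    return cases


def select_misclassified_cases(clf: TaskClassifier,
                               ds: LabeledDataset) -> list[tuple[ActivationMap, int]]:
    """Misclassified maps, each targeted at its true class."""
    pred = clf.predict(ds)
    labels = ds.labels_array()
    return [(m, int(y)) for m, p, y in zip(ds.maps, pred, labels) if p != y]


def perturbation_sweep(
    gen: Generator,
    clf: TaskClassifier,
    cases: Sequence[tuple[ActivationMap, int]],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    ranking: str = "absolute",
) -> tuple[PerturbationSweepResult, list[CounterfactualExplanation]]:
    """Count target-class assignments of normalize(original + CE_alpha).

    Each case is an (original map, target class) pair with target different
    from the classifier's assignment on the original.
    """
    if len(cases) == 0:
        raise ValueError("empty case set")
    explanations = []
    for amap, target in cases:
        explanations.append(explain(gen, clf, amap, target))
    counts = []
    for alpha in alphas:
        assigned = 0
        for exp in explanations:
            ce_a = threshold_ce(exp.ce, alpha, exp.original.mask, ranking)
            new = exp.original.values + ce_a
            new_map = minmax_normalize(
                ActivationMap(np.where(exp.original.mask, new, 0.0),
                              exp.original.mask)
            )
            if int(clf.predict(new_map)[0]) == exp.target_class:
                assigned += 1
        counts.append(assigned)
    return (
        PerturbationSweepResult(list(alphas), counts, len(explanations)),
        explanations,
    )


def control_delta_ave(ds: LabeledDataset, source_class: int,
                      target_class: int) -> np.ndarray:
    """Masked difference of class means: mean(target maps) - mean(source maps)."""
    delta = ds.class_mean(target_class) - ds.class_mean(source_class)
    return np.where(ds.mask, delta, 0.0)


def kappa_search(
    clf: TaskClassifier,
    cases: Sequence[tuple[ActivationMap, int]],
    delta_ave: np.ndarray,
    grid: Sequence[float] = KAPPA_GRID,
) -> tuple[float, int]:
    """Gain maximizing target assignments of normalize(original + kappa * DeltaAve).

    All cases must share one (source, target) pair (one Delta-Ave map).
    Ties resolve to the smallest kappa.
    """
    if len(cases) == 0:
        raise ValueError("empty case set")
    best_kappa, best_count = None, -1
    for kappa in grid:
        count = 0
        for amap, target in cases:
            new = amap.values + kappa * delta_ave
            new_map = minmax_normalize(
                ActivationMap(np.where(amap.mask, new, 0.0), amap.mask)
            )
            if int(clf.predict(new_map)[0]) == target:
                count += 1
        if count > best_count:
            best_kappa, best_count = float(kappa), count
    return best_kappa, best_count


def run_control_analysis(
    clf: TaskClassifier,
    ds: LabeledDataset,
    cases: Sequence[tuple[ActivationMap, int]],
    grid: Sequence[float] = KAPPA_GRID,
) -> ControlResult:
    """Kappa-tuned class-mean control over all (source, target) pairs in cases."""
    result = ControlResult(n_cases=len(cases))
    by_pair: dict[tuple[int, int], list] = {}
    for amap, target in cases:
        by_pair.setdefault((int(amap.label), target), []).append((amap, target))
    for (src, tgt), pair_cases in by_pair.items():
        delta = control_delta_ave(ds, src, tgt)
        kappa, count = kappa_search(clf, pair_cases, delta, grid)
        result.pair_results[(src, tgt)] = {
            "kappa": kappa, "count": count, "n_pair": len(pair_cases),
        }
        result.total_count += count
    return result


def explain_misclassification(
    gen: Generator,
    clf: TaskClassifier,
    ds: LabeledDataset,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    ranking: str = "absolute",
    with_control: bool = True,
):
    """Full incorrect-case protocol: CE toward the true class, sweep, control."""
    cases = select_misclassified_cases(clf, ds)
    if len(cases) == 0:
        return PerturbationSweepResult(list(alphas), [0] * len(alphas), 0), [], None
    for amap, target in cases:
        if int(clf.predict(amap)[0]) == target:
            raise ValueError(f"case {amap.id} is not actually misclassified")
    sweep, explanations = perturbation_sweep(gen, clf, cases, alphas, ranking)
    control = run_control_analysis(clf, ds, cases) if with_control else None
    return sweep, explanations, control
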