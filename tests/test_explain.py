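"""Counterfactual-explanation construction, thresholding, sweep and controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurocf.data import ActivationMap, LabeledDataset
from neurocf.explain import (
    KAPPA_GRID,
    control_delta_ave,
    explain,
    kappa_search,
    perturbation_sweep,
    select_correct_cases,
    select_misclassified_cases,
    threshold_ce,
)


class StubClassifier:
    """Predicts via a caller-supplied function of the (normalized) map values."""

    def __init__(self, fn, K=3):
        self.fn = fn
        self.cfg = type("C", (), {"K": K})

    def predict(self, maps):
        if isinstance(maps, ActivationMap):
            maps = [maps]
        if isinstance(maps, LabeledDataset):
            maps = maps.maps
        return np.array([self.fn(m.values) for m in maps])


class TestExplain:
    def test_identity_generator_zero_ce_and_additivity(self, identity_gen, tiny_ds):
        clf = StubClassifier(lambda v: 0)
        ce = explain(identity_gen, clf, tiny_ds.maps[0], target=2)
        assert np.allclose(ce.ce, 0.0)
        assert np.array_equal(ce.original.values + ce.ce, ce.counterfactual.values)

    def test_additivity_exact_for_real_generator(self, tiny_gen, tiny_ds):
        clf = StubClassifier(lambda v: 0)
        ce = explain(tiny_gen, clf, tiny_ds.maps[0], target=1)
        assert np.array_equal(ce.original.values + ce.ce, ce.counterfactual.values)
        assert np.all(ce.ce[~tiny_ds.mask] == 0.0)

    def test_target_equal_source_rejected(self, identity_gen, tiny_ds):
        clf = StubClassifier(lambda v: 2)
        with pytest.raises(ValueError, match="differ"):
            explain(identity_gen, clf, tiny_ds.maps[0], target=2)


class TestThresholdCe:
    def _setup(self):
        mask = np.ones((1, 5), dtype=bool)
        ce = np.array([[0.5, -1.0, 2.0, -3.0, 4.0]])
        return ce, mask

    def test_alpha_zero_unchanged(self):
        ce, mask = self._setup()
        assert np.array_equal(threshold_ce(ce, 0.0, mask), ce)

    def test_alpha_100_all_zero(self):
        ce, mask = self._setup()
        assert np.all(threshold_ce(ce, 100.0, mask) == 0.0)

    def test_alpha_40_zeroes_two_smallest_magnitudes(self):
        # |ce| = {0.5, 1, 2, 3, 4}; the interpolated 40th percentile is 1.6,
        # so exactly the two smallest-magnitude pixels are zeroed
        ce, mask = self._setup()
        out = threshold_ce(ce, 40.0, mask, ranking="absolute")
        assert np.percentile(np.abs(ce[mask]), 40.0) == pytest.approx(1.6)
        assert np.array_equal(out, np.array([[0.0, 0.0, 2.0, -3.0, 4.0]]))

    def test_signed_ranking_differs_from_absolute(self):
        ce, mask = self._setup()
        signed = threshold_ce(ce, 40.0, mask, ranking="signed")
        # signed 40th percentile of {-3,-1,0.5,2,4} is -0.1 -> negatives zeroed
        assert np.array_equal(signed, np.array([[0.5, 0.0, 2.0, 0.0, 4.0]]))

    def test_matches_brute_force_percentile_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            ce = rng.standard_normal((5, 10))
            mask = rng.uniform(size=(5, 10)) > 0.3
            if not mask.any():
                continue
            alpha = float(rng.uniform(1, 99))
            out = threshold_ce(ce, alpha, mask)
            cut = np.percentile(np.abs(ce[mask]), alpha)
            expected = np.where(mask & (np.abs(ce) >= cut), ce, 0.0)
            assert np.array_equal(out, expected)

    @given(alphas=st.lists(st.floats(0, 100), min_size=2, max_size=5))
    @settings(max_examples=30, deadline=None)
    def test_support_shrinks_as_alpha_grows(self, alphas):
        rng = np.random.default_rng(7)
        ce = rng.standard_normal((4, 6))
        mask = np.ones((4, 6), dtype=bool)
        for a_lo, a_hi in zip(sorted(alphas), sorted(alphas)[1:]):
            lo = threshold_ce(ce, a_lo, mask) != 0
            hi = threshold_ce(ce, a_hi, mask) != 0
            assert np.all(lo | ~hi)  # support(hi) subset of support(lo)

    def test_alpha_out_of_range(self):
        ce, mask = self._setup()
        with pytest.raises(ValueError):
            threshold_ce(ce, -1, mask)
        with pytest.raises(ValueError):
            threshold_ce(ce, 101, mask)


class TestPerturbationSweep:
    def test_alpha100_count_zero_by_construction(self, tiny_gen, tiny_ds):
        # at alpha=100 the reconstruction is the original, whose assigned
        # class differs from the target under both protocols
        clf = StubClassifier(lambda v: 0, K=3)
        cases = [(m, 1) for m in tiny_ds.maps[:5]]
        sweep, _ = perturbation_sweep(tiny_gen, clf, cases, alphas=(0.0, 100.0))
        assert sweep.counts[-1] == 0

    def test_alpha0_equals_counterfactual_classification(self, tiny_gen, tiny_ds):
        # split maps around the median mean so both stub classes occur
        cut = float(np.median([m.values[tiny_ds.mask].mean()
                               for m in tiny_ds.maps[:6]]))

        def fn(v):
            return int(v[tiny_ds.mask].mean() > cut)

        clf = StubClassifier(fn, K=3)
        cases = [(m, 1) for m in tiny_ds.maps[:6] if fn(m.values) != 1]
        assert cases
        sweep, explanations = perturbation_sweep(tiny_gen, clf, cases, alphas=(0.0,))
        direct = sum(
            int(fn(e.counterfactual.values) == 1) for e in explanations
        )
        assert sweep.counts[0] == direct

    def test_empty_case_set_rejected(self, tiny_gen):
        clf = StubClassifier(lambda v: 0)
        with pytest.raises(ValueError, match="empty"):
            perturbation_sweep(tiny_gen, clf, [])


class TestControl:
    def test_delta_ave_source_equals_target_is_zero(self, tiny_ds):
        delta = control_delta_ave(tiny_ds, 1, 1)
        assert np.allclose(delta, 0.0)

    def test_delta_ave_one_map_per_class(self, tiny_ds):
        sub = tiny_ds.subset([0, 5])  # one map of class 0 and one of class 1
        delta = control_delta_ave(sub, 0, 1)
        expected = sub.maps[1].values - sub.maps[0].values
        assert np.allclose(delta[sub.mask], expected[sub.mask])

    def test_delta_ave_invariant_under_duplication(self, tiny_ds):
        doubled = LabeledDataset(tiny_ds.maps + tiny_ds.maps, tiny_ds.class_names)
        assert np.allclose(control_delta_ave(tiny_ds, 0, 2),
                           control_delta_ave(doubled, 0, 2))


class TestKappaSearch:
    def test_kappa_zero_matches_original_classification(self, tiny_ds):
        clf = StubClassifier(lambda v: 0, K=3)
        cases = [(m, 0) for m in tiny_ds.maps[:4]]
        delta = np.zeros_like(tiny_ds.maps[0].values)
        kappa, count = kappa_search(clf, cases, delta, grid=(0.0,))
        assert kappa == 0.0 and count == 4

    def test_constructed_threshold_flips_at_1_3(self):
        # normalized probe pixel crosses 0.33 exactly at kappa = 1.3
        mask = np.ones((2, 2), dtype=bool)
        base = np.array([[0.0, 1.0], [0.2, 0.5]])
        amap = ActivationMap(base, mask, label=0)
        delta = np.zeros((2, 2))
        delta[1, 0] = 0.1
        clf = StubClassifier(lambda v: 1 if v[1, 0] >= 0.33 else 0, K=2)
        kappa, count = kappa_search(clf, [(amap, 1)], delta)
        assert kappa == pytest.approx(1.3)
        assert count == 1

    def test_equals_brute_force_grid_maximization(self, tiny_ds):
        rng = np.random.default_rng(3)
        clf = StubClassifier(
            lambda v: int(v[tiny_ds.mask].mean() * 10) % 3, K=3
        )
        cases = [(m, 1) for m in tiny_ds.maps[:6]]
        delta = rng.standard_normal(tiny_ds.maps[0].shape) * 0.05
        delta[~tiny_ds.mask] = 0.0
        kappa, count = kappa_search(clf, cases, delta)

        def count_at(k):
            from neurocf.data import minmax_normalize

            c = 0
            for amap, target in cases:
                vals = np.where(tiny_ds.mask, amap.values + k * delta, 0.0)
                nm = minmax_normalize(ActivationMap(vals, tiny_ds.mask))
                c += int(clf.predict(nm)[0] == target)
            return c

        per_kappa = [count_at(k) for k in KAPPA_GRID]
        assert count == max(per_kappa)
        assert kappa == KAPPA_GRID[int(np.argmax(per_kappa))]  # smallest argmax


class TestCaseSelection:
    def test_correct_cases_have_incorrect_targets(self, tiny_ds):
        clf = StubClassifier(lambda v: 0, K=3)
        rng = np.random.default_rng(0)
        cases = select_correct_cases(clf, tiny_ds, rng)
        # only class-0 maps are correctly classified by this stub
        assert len(cases) == 5
        assert all(t != 0 for _, t in cases)

    def test_misclassified_cases_target_true_class(self, tiny_ds):
        clf = StubClassifier(lambda v: 0, K=3)
        cases = select_misclassified_cases(clf, tiny_ds)
        assert len(cases) == 10
        assert all(m.label == t and t != 0 for m, t in cases)
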