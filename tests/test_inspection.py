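"""Inspector ensemble: batch partition, scoring algebra, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasmote.exceptions import ConfigurationError
from sasmote.inspection import (
    filter_by_uncertainty,
    num_inspectors,
    train_inspectors,
    uncertainty_score,
)
from sasmote.sampler import SyntheticBatch

from conftest import make_dataset, small_forest_factory


def make_batch(points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = len(points)
    return SyntheticBatch(points, np.zeros(m, int), np.ones(m, int),
                          np.full(m, 0.5), np.ones(m, int))


class TestNumInspectors:
    @pytest.mark.parametrize(
        "n_min,n_maj,expect",
        [(121, 963, 8), (677, 10097, 15), (100, 100, 1), (10, 25, 3), (10, 24, 2)],
        ids=["ratio-7.96", "ratio-14.92", "balanced", "half-up-2.5", "ratio-2.4"],
    )
    def test_half_up_rounding(self, n_min, n_maj, expect):
        assert num_inspectors(n_min, n_maj) == expect

    def test_degenerate_rejected(self):
        with pytest.raises(ConfigurationError):
            num_inspectors(0, 10)


class FixedVote:
    """Fake inspector predicting a constant label."""

    n_features_in_ = 2

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)


def fixed_ensemble(labels):
    from sasmote.inspection import InspectorEnsemble

    return InspectorEnsemble(
        inspectors=[FixedVote(l) for l in labels],
        batch_assignment=[np.array([i]) for i in range(len(labels))],
        majority_label="maj",
    )


class TestUncertaintyScore:
    def test_half_votes(self):
        ens = fixed_ensemble(["maj", "maj", "min", "min"])
        np.testing.assert_array_equal(
            uncertainty_score(ens, np.zeros((3, 2))), [0.5, 0.5, 0.5]
        )

    @pytest.mark.parametrize("votes,expect",
                             [(["min"] * 4, 0.0), (["maj"] * 4, 1.0)])
    def test_bounds(self, votes, expect):
        ens = fixed_ensemble(votes)
        assert uncertainty_score(ens, np.zeros((1, 2)))[0] == expect

    def test_scores_are_multiples_of_inverse_m(self, blobs_separated):
        ds, _ = blobs_separated
        rng = np.random.default_rng(0)
        ens = train_inspectors(ds, 4, rng, classifier_factory=small_forest_factory)
        scores = uncertainty_score(ens, ds.features[:20])
        np.testing.assert_allclose(scores * 4, np.round(scores * 4), atol=1e-12)
        assert np.all((scores >= 0) & (scores <= 1))


class TestTrainInspectors:
    def test_partition_is_exact_and_near_equal(self, crescent):
        ds, _ = crescent
        ens = train_inspectors(ds, 8, np.random.default_rng(1),
                               classifier_factory=small_forest_factory)
        sizes = [len(b) for b in ens.batch_assignment]
        assert sum(sizes) == 500
        assert max(sizes) - min(sizes) <= 1
        union = np.sort(np.concatenate(ens.batch_assignment))
        np.testing.assert_array_equal(union, ds.majority_indices)  # disjoint + complete

    def test_case1_shaped_batch_sizes(self):
        """963 majority rows split 8 ways -> three batches of 121, five of 120."""
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(121, int), np.zeros(963, int)]
        ds = make_dataset(rng.normal(size=(1084, 3)), y)
        ens = train_inspectors(ds, 8, rng, classifier_factory=small_forest_factory)
        sizes = sorted(len(b) for b in ens.batch_assignment)
        assert sizes == [120] * 5 + [121] * 3

    def test_single_inspector_sees_everything(self, blobs_separated):
        ds, _ = blobs_separated
        ens = train_inspectors(ds, 1, np.random.default_rng(2),
                               classifier_factory=small_forest_factory)
        assert ens.M == 1
        np.testing.assert_array_equal(ens.batch_assignment[0], ds.majority_indices)

    def test_deterministic_partition(self, crescent):
        ds, _ = crescent
        e1 = train_inspectors(ds, 5, np.random.default_rng(7),
                              classifier_factory=small_forest_factory)
        e2 = train_inspectors(ds, 5, np.random.default_rng(7),
                              classifier_factory=small_forest_factory)
        for a, b in zip(e1.batch_assignment, e2.batch_assignment):
            np.testing.assert_array_equal(a, b)

    def test_too_many_batches_rejected(self, blobs_separated):
        ds, _ = blobs_separated
        with pytest.raises(ConfigurationError):
            train_inspectors(ds, 10_000, np.random.default_rng(0))

    def test_deep_minority_points_score_zero(self, blobs_separated):
        """With a wide margin, points at the minority mean are unanimously
        recognized (median score 0 across seeds; rare tree noise allowed)."""
        ds, _ = blobs_separated
        target = ds.minority_features.mean(axis=0, keepdims=True)
        meds = []
        for seed in range(10):
            ens = train_inspectors(ds, 4, np.random.default_rng(seed),
                                   classifier_factory=small_forest_factory)
            meds.append(uncertainty_score(ens, target)[0])
        assert np.median(meds) == 0.0


class TestFilterByUncertainty:
    def test_threshold_is_strict(self):
        batch = make_batch(np.zeros((3, 2)))
        kept = filter_by_uncertainty(batch, np.array([0.25, 0.5, 0.75]), 0.5)
        assert len(kept) == 2  # score == T survives; only strictly higher is dropped

    @pytest.mark.parametrize("thr,expect", [(1.0, 4), (0.0, 1)])
    def test_boundary_thresholds(self, thr, expect):
        batch = make_batch(np.zeros((4, 2)))
        kept = filter_by_uncertainty(batch, np.array([0.0, 0.4, 0.8, 1.0]), thr)
        assert len(kept) == expect

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            filter_by_uncertainty(make_batch(np.zeros((1, 2))), np.array([0.5]), 1.5)

    @given(st.lists(st.sampled_from([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]),
                    min_size=1, max_size=30),
           st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, scores, t1, t2):
        lo, hi = sorted([t1, t2])
        batch = make_batch(np.zeros((len(scores), 2)))
        kept_lo = filter_by_uncertainty(batch, np.array(scores), lo)
        kept_hi = filter_by_uncertainty(batch, np.array(scores), hi)
        assert len(kept_lo) <= len(kept_hi)
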