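"""Residue-wise AUC, weight grid search, and the cutoff sweep."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldunits import (
    FeatureTrack,
    LabeledResidueSet,
    grid_search_weights,
    residue_auc,
    threshold_sweep,
)
from foldunits.features import FEATURE_NAMES


def pair_counting_auc(labels, scores):
    """Independent oracle: fraction of positive-negative pairs ordered
    correctly, ties worth half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestResidueAuc:
    @pytest.mark.parametrize(
        "labels, scores, expected",
        [
            ([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 1.0),
            ([1, 0], [0.5, 0.5], 0.5),
            ([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1], 0.75),
        ],
    )
    def test_known_values(self, labels, scores, expected):
        assert residue_auc(np.array(labels), np.array(scores)) == pytest.approx(expected)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            residue_auc(np.array([1, 1]), np.array([0.5, 0.6]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.uniform(size=50) < 0.4
        if labels.all() or not labels.any():
            labels[0], labels[1] = True, False
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=50)
        assert residue_auc(labels, scores) == pytest.approx(
            pair_counting_auc(labels, scores)
        )

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.uniform(size=200) < 0.3
        labels[0], labels[1] = True, False
        scores = rng.uniform(size=200)
        assert residue_auc(labels, scores) == pytest.approx(
            residue_auc(labels, np.exp(3 * scores))
        )


def make_set(features, labels):
    return LabeledResidueSet(np.asarray(features, float), np.asarray(labels, bool))


class TestGridSearch:
    def test_single_informative_feature_recovered(self, rng):
        n = 200
        order = rng.uniform(size=n)
        labels = order > 0.5
        features = rng.uniform(size=(n, 5))
        features[:, 0] = order
        weights, auc = grid_search_weights(make_set(features, labels), (0.0, 1.0))
        assert weights.as_tuple() == (1.0, 0.0, 0.0, 0.0, 0.0)
        assert auc == pytest.approx(1.0)

    def test_single_combination_grid(self, rng):
        features = rng.uniform(size=(60, 5))
        labels = rng.uniform(size=60) < 0.5
        labels[0], labels[1] = True, False
        weights, auc = grid_search_weights(make_set(features, labels), (1.0,))
        assert weights.as_tuple() == (1.0, 1.0, 1.0, 1.0, 1.0)
        scores = features.mean(axis=1)
        assert auc == pytest.approx(residue_auc(labels, scores))

    def test_matches_exhaustive_oracle_on_three_feature_toy(self, rng):
        # only three features carry candidate mass > 0; oracle re-evaluates
        # every non-zero combination independently
        n = 20
        features = np.zeros((n, 5))
        features[:, :3] = rng.uniform(size=(n, 3))
        labels = features[:, 1] > 0.4
        labels[0] = ~labels[0]  # ensure both classes
        grid = {
            name: ((0.0, 0.5, 1.0) if i < 3 else (0.0,))
            for i, name in enumerate(FEATURE_NAMES)
        }
        data = make_set(features, labels)
        weights, auc = grid_search_weights(data, grid)

        best = None
        for combo in product((0.0, 0.5, 1.0), repeat=3):
            w = np.array(combo + (0.0, 0.0))
            if w.sum() == 0:
                continue
            a = pair_counting_auc(labels, features @ w / w.sum())
            key = (-round(a, 10), w.sum(), tuple(w))
            if best is None or key < best:
                best = key
        assert auc == pytest.approx(-best[0])
        assert weights.as_tuple() == best[2]

    def test_result_beats_every_single_feature(self, rng):
        features = rng.uniform(size=(100, 5))
        labels = (features[:, 0] + features[:, 2]) > 1.0
        labels[0] = ~labels[0]
        data = make_set(features, labels)
        _, auc = grid_search_weights(data, (0.0, 1.0))
        for i in range(5):
            assert auc >= residue_auc(labels, features[:, i]) - 1e-12

    def test_weight_scaling_leaves_auc_unchanged(self, rng):
        features = rng.uniform(size=(80, 5))
        labels = rng.uniform(size=80) < 0.5
        labels[0], labels[1] = True, False
        w = np.array([0.8, 1.0, 0.6, 0.1, 0.1])
        a1 = residue_auc(labels, features @ w / w.sum())
        a2 = residue_auc(labels, features @ (3 * w) / (3 * w).sum())
        assert a1 == pytest.approx(a2)

    def test_from_tracks_excludes_masked_residues(self):
        tracks = {
            "p": {
                name: FeatureTrack(name, np.linspace(0, 1, 10))
                for name in FEATURE_NAMES
            }
        }
        labels = {"p": np.array([0] * 5 + [1] * 5, bool)}
        masks = {"p": np.array([1] * 3 + [0] * 7, bool)}
        data = LabeledResidueSet.from_tracks(tracks, labels, masks)
        assert data.labels.size == 7


class TestThresholdSweep:
    def test_perfect_separation(self):
        labels = np.array([1, 1, 0, 0], bool)
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        df = threshold_sweep(labels, scores)
        best = df[df["best"]].iloc[0]
        assert best["balanced_accuracy"] == pytest.approx(100.0)
        assert 0.2 < best["cutoff"] <= 0.8

    def test_two_point_separable(self):
        df = threshold_sweep(np.array([1, 0], bool), np.array([0.9, 0.1]))
        best = df[df["best"]].iloc[0]
        assert best["sensitivity"] == pytest.approx(100.0)
        assert best["specificity"] == pytest.approx(100.0)
        assert 0.1 < best["cutoff"] <= 0.9

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(2024)
        labels = rng.uniform(size=10_000) < 0.5
        scores = rng.uniform(size=10_000)
        df = threshold_sweep(labels, scores)
        best = df[df["best"]].iloc[0]
        assert best["balanced_accuracy"] == pytest.approx(50.0, abs=3.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            threshold_sweep(np.array([True, True]), np.array([0.1, 0.2]))
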