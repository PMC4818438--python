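"""Target scoring and density-grid unit calling.

The calling algorithm is checked against a brute-force oracle: at grid
size 1 the called units must be exactly the maximal runs of consecutive
above-cutoff residues that pass the length filter.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldunits import (
    CallerConfig,
    DomainAnnotation,
    FeatureTrack,
    Interval,
    MaskKind,
    ProteinRecord,
    RegionMask,
    SourceClass,
    TargetScoreProfile,
    UnitKind,
    WeightVector,
    call_units,
    grid_averages,
    predict,
    target_score,
)
from foldunits.features import FEATURE_NAMES


def flat_tracks(length, value):
    return {
        name: FeatureTrack(name, np.full(length, float(value)))
        for name in FEATURE_NAMES
    }


def profile(scores, masked=None):
    scores = np.asarray(scores, float)
    masked = (
        np.zeros(scores.size, bool) if masked is None else np.asarray(masked, bool)
    )
    return TargetScoreProfile(scores, masked)


def maximal_runs_oracle(scores, masked, cutoff, min_length):
    """Independent enumeration: maximal runs of consecutive unmasked
    residues with score > cutoff, kept when long enough."""
    runs = []
    start = None
    for i, s in enumerate(scores):
        ok = (not masked[i]) and s > cutoff
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(scores)))
    return [Interval(a, b) for a, b in runs if b - a + 1 >= min_length]


class TestTargetScore:
    def test_all_ones_normalizes_to_one(self):
        prof = target_score(flat_tracks(30, 1.0))
        assert np.allclose(prof.scores, 1.0)

    def test_all_zeros(self):
        prof = target_score(flat_tracks(30, 0.0))
        assert np.allclose(prof.scores, 0.0)

    def test_default_weights_flat_half_tracks(self):
        # (0.5 * 2.6) / 2.6 = 0.5 regardless of weights
        prof = target_score(flat_tracks(10, 0.5))
        assert np.allclose(prof.scores, 0.5)

    def test_masked_positions_score_exactly_zero(self):
        mask = RegionMask(MaskKind.CONSENSUS_DOMAIN, (Interval(5, 10),))
        prof = target_score(flat_tracks(20, 1.0), masks=[mask])
        assert np.all(prof.scores[4:10] == 0.0)
        assert np.all(prof.masked[4:10])
        assert np.allclose(prof.scores[:4], 1.0)

    def test_unit_weight_single_track_reproduces_track(self, rng):
        tracks = flat_tracks(40, 0.0)
        vals = rng.uniform(0, 1, 40)
        tracks["order"] = FeatureTrack("order", vals)
        w = WeightVector(1.0, 0.0, 0.0, 0.0, 0.0)
        prof = target_score(tracks, w)
        assert np.allclose(prof.scores, vals)

    def test_unnormalized_score_scales_with_weight_sum(self):
        prof = target_score(flat_tracks(10, 1.0), normalize=False)
        assert np.allclose(prof.scores, 2.6)

    def test_length_mismatch_errors(self):
        tracks = flat_tracks(10, 0.5)
        tracks["order"] = FeatureTrack("order", np.full(9, 0.5))
        with pytest.raises(ValueError, match="mismatch"):
            target_score(tracks)


class TestGridAverages:
    def test_even_split(self):
        out = grid_averages(profile(np.ones(10)), 5)
        assert [(iv.start, iv.end) for iv, _ in out] == [(1, 5), (6, 10)]
        assert [m for _, m in out] == [1.0, 1.0]

    def test_partial_tail_grid(self):
        out = grid_averages(profile([1, 1, 1, 1, 1, 0, 0]), 5)
        assert [(iv.start, iv.end) for iv, _ in out] == [(1, 5), (6, 7)]
        assert out[0][1] == pytest.approx(1.0)
        assert out[1][1] == pytest.approx(0.0)

    def test_protein_shorter_than_grid(self):
        out = grid_averages(profile([0.2, 0.4, 0.6]), 5)
        assert [(iv.start, iv.end) for iv, _ in out] == [(1, 3)]
        assert out[0][1] == pytest.approx(0.4)


class TestCallUnits:
    def test_uniform_high_profile_gives_one_full_unit(self):
        units = call_units(profile(np.ones(100)))
        assert len(units) == 1
        assert units[0].interval == Interval(1, 100)
        assert units[0].mean_score == pytest.approx(1.0)
        assert units[0].kind is UnitKind.PUTATIVE_UNIT

    def test_below_cutoff_everywhere_gives_nothing(self):
        assert call_units(profile(np.full(100, 0.3))) == []

    def test_high_block_then_zero_stops_at_block_edge(self):
        scores = np.concatenate([np.full(45, 0.9), np.zeros(55)])
        units = call_units(profile(scores))
        assert [u.interval for u in units] == [Interval(1, 45)]
        assert units[0].mean_score == pytest.approx(0.9)

    def test_short_high_block_filtered_but_claimed(self):
        scores = np.concatenate([np.full(30, 0.9), np.zeros(70)])
        assert call_units(profile(scores)) == []

    def test_two_separate_blocks_called_separately(self):
        scores = np.zeros(200)
        scores[9:59] = 0.9   # residues 10..59
        scores[119:179] = 0.8  # residues 120..179
        units = call_units(profile(scores))
        # grid 5: partial-coverage edge grids [6,10] / [116,120] average
        # below the cutoff and are not absorbed; [56,60] and [176,180] are
        assert [u.interval for u in units] == [Interval(11, 60), Interval(121, 180)]

    def test_units_never_enter_masks(self):
        scores = np.full(120, 0.9)
        masked = np.zeros(120, bool)
        masked[50:60] = True
        scores[50:60] = 0.0
        units = call_units(profile(scores, masked))
        for u in units:
            assert not masked[u.interval.start - 1 : u.interval.end].any()

    def test_emitted_units_satisfy_contract(self, rng):
        config = CallerConfig()
        scores = rng.uniform(0, 1, 300)
        masked = rng.uniform(0, 1, 300) < 0.1
        scores[masked] = 0.0
        units = call_units(profile(scores, masked), config)
        for a, b in zip(units, units[1:]):
            assert a.interval.end < b.interval.start
        for u in units:
            assert u.mean_score > config.score_cutoff
            assert u.interval.length > 40
            assert not masked[u.interval.start - 1 : u.interval.end].any()


@given(st.data())
@settings(max_examples=150, derandomize=True, deadline=None)
def test_grid_one_matches_maximal_run_oracle(data):
    n = data.draw(st.integers(5, 60))
    scores = np.array(
        data.draw(
            st.lists(
                st.sampled_from([0.0, 0.3, 0.51, 0.52, 0.53, 0.7, 0.9, 1.0]),
                min_size=n, max_size=n,
            )
        )
    )
    masked = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    scores[masked] = 0.0
    min_length = data.draw(st.integers(1, 15))
    config = CallerConfig(grid_size=1, score_cutoff=0.52, min_length=min_length)
    units = call_units(profile(scores, masked), config)
    assert [u.interval for u in units] == maximal_runs_oracle(
        scores, masked, 0.52, min_length
    )


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_raising_cutoff_never_increases_coverage(seed):
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0, 1, 200)
    prof = profile(scores)
    coverages = []
    for cutoff in (0.3, 0.5, 0.7):
        units = call_units(prof, CallerConfig(score_cutoff=cutoff))
        coverages.append(sum(u.interval.length for u in units))
    assert coverages == sorted(coverages, reverse=True)


class TestPredict:
    protein = ProteinRecord("p", "A" * 200)

    def test_annotation_with_flat_zero_tracks_gives_domain_only(self):
        anns = [DomainAnnotation(Interval(20, 80), SourceClass.SEQUENCE_BASED)]
        units, prof = predict(self.protein, anns, flat_tracks(200, 0.0))
        assert [u.kind for u in units] == [UnitKind.CONSENSUS_DOMAIN]
        assert units[0].mean_score == 0.0
        assert np.all(prof.masked[19:80])

    def test_no_annotations_high_tracks_gives_full_span_unit(self):
        units, _ = predict(self.protein, [], flat_tracks(200, 1.0))
        assert [u.interval for u in units] == [Interval(1, 200)]
        assert units[0].kind is UnitKind.PUTATIVE_UNIT

    def test_domain_and_distant_high_region_both_reported(self):
        anns = [DomainAnnotation(Interval(1, 60), SourceClass.SEQUENCE_BASED)]
        tracks = flat_tracks(200, 0.0)
        for name in FEATURE_NAMES:
            vals = tracks[name].values.copy()
            vals[100:160] = 1.0  # residues 101..160
            tracks[name] = FeatureTrack(name, vals)
        units, _ = predict(self.protein, anns, tracks)
        kinds = [u.kind for u in units]
        assert kinds == [UnitKind.CONSENSUS_DOMAIN, UnitKind.PUTATIVE_UNIT]
        a, b = units
        assert a.interval.end < b.interval.start
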