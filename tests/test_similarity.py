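"""Dice, centroid extraction, MMED and the SISS composite."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sulciscore import (
    CentroidPath,
    SimilarityScore,
    dice,
    extract_centroid,
    mmed,
    normalize_mmed,
    score_pair,
    siss,
)

pixel_sets = st.sets(
    st.tuples(st.integers(0, 49), st.integers(0, 49)), min_size=1, max_size=60
)


class TestDice:
    def test_identical_masks_score_one(self, make_mask):
        a = make_mask({(1, 1), (2, 2), (3, 3)})
        assert dice(a, a) == 1.0

    def test_disjoint_masks_score_zero(self, make_mask):
        a = make_mask({(1, 1)})
        b = make_mask({(5, 5)})
        assert dice(a, b) == 0.0

    def test_half_overlap(self, make_mask):
        a = make_mask({(0, 0), (0, 1)})
        b = make_mask({(0, 1), (0, 2)})
        assert dice(a, b) == 0.5

    def test_shape_mismatch_rejected(self, make_mask):
        a = make_mask({(1, 1)})
        b = make_mask({(1, 1)}, shape=(60, 60))
        with pytest.raises(ValueError, match="shape"):
            dice(a, b)

    def test_empty_operand_rejected(self, make_mask):
        with pytest.raises(ValueError, match="empty"):
            dice(make_mask(set()), make_mask({(1, 1)}))

    @given(pixel_sets, pixel_sets)
    def test_symmetric_bounded_and_extremes(self, pa, pb):
        from sulciscore import BinaryMask

        a = BinaryMask("superior", "left", "S.C", "R1", (50, 50), frozenset(pa))
        b = BinaryMask("superior", "left", "S.C", "R2", (50, 50), frozenset(pb))
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == (a.pixels == b.pixels)
        assert (d == 0.0) == (not a.pixels & b.pixels)


class TestExtractCentroid:
    def test_straight_wide_bar_collapses_to_central_row(self, make_mask):
        bar = make_mask({(r, c) for r in (4, 5, 6) for c in range(10)})
        path = extract_centroid(bar)
        assert path.axis == "horizontal"
        assert path.points == tuple((5, c) for c in range(10))

    def test_thin_curve_is_a_fixed_point(self, make_mask):
        pixels = {(10 + int(3 * math.sin(c / 3)), c) for c in range(20)}
        path = extract_centroid(make_mask(pixels))
        assert set(path.points) == pixels
        assert len(path) == 20

    def test_diagonal_band_tracks_midline(self, make_mask):
        band = {(c // 2 + dr, c) for c in range(30) for dr in (0, 1, 2)}
        mask = make_mask(band)
        path = extract_centroid(mask)
        assert path.axis == "horizontal"
        assert len(path) == 30
        arr = mask.to_array()
        for r, c in path.points:
            assert (r, c) in band
            # brute-force per-column pixel mean as the midline oracle
            midline = arr[arr[:, 1] == c, 0].mean()
            assert abs(r - midline) <= 1

    def test_vertical_stroke_uses_row_axis(self, make_mask):
        stroke = {(r, 10 + dr) for r in range(20) for dr in (0, 1, 2)}
        path = extract_centroid(make_mask(stroke))
        assert path.axis == "vertical"
        assert path.points == tuple((r, 11) for r in range(20))

    def test_degenerate_cloud_falls_back_to_transverse_mean(self, make_mask):
        # two occupied columns only: below the smoother's minimum support
        cloud = {(r, c) for r in range(10) for c in (5, 6)}
        path = extract_centroid(make_mask(cloud))
        assert path.axis == "vertical"
        assert all(c in (5, 6) for _, c in path.points)

    def test_empty_mask_rejected(self, make_mask):
        with pytest.raises(ValueError, match="empty"):
            extract_centroid(make_mask(set()))

    def test_mean_smoother_equals_per_column_mean(self, make_mask):
        rng = np.random.default_rng(3)
        pixels = set()
        for c in range(25):
            center = 20 + 5 * math.sin(c / 4)
            for _ in range(4):
                pixels.add((int(center + rng.integers(-2, 3)), c))
        mask = make_mask(pixels)
        path = extract_centroid(mask, smoother="mean")
        arr = mask.to_array()
        for r, c in path.points:
            expected = arr[arr[:, 1] == c, 0].mean()
            assert r == int(np.floor(expected + 0.5))


class TestCentroidPathInvariants:
    def test_one_point_per_independent_coordinate_enforced(self):
        with pytest.raises(ValueError, match="one point per"):
            CentroidPath(((0, 1), (2, 1)), "horizontal")

    def test_sorted_order_enforced(self):
        with pytest.raises(ValueError, match="sorted"):
            CentroidPath(((0, 2), (0, 1)), "horizontal")


class TestMmed:
    def test_centroid_inside_reference_gives_zero(self, make_mask):
        ref = make_mask({(5, c) for c in range(10)})
        path = CentroidPath(tuple((5, c) for c in range(10)), "horizontal")
        assert mmed(path, ref) == 0.0

    def test_single_point_pythagorean_distance(self, make_mask):
        path = CentroidPath(((0, 0),), "horizontal")
        assert mmed(path, make_mask({(3, 4)})) == pytest.approx(5.0)

    def test_mean_of_minima(self, make_mask):
        path = CentroidPath(((0, 0), (0, 10)), "horizontal")
        assert mmed(path, make_mask({(0, 0)})) == pytest.approx(5.0)

    def test_matches_brute_force_oracle_on_random_pairs(self, make_mask):
        rng = np.random.default_rng(11)
        for _ in range(25):
            ref_pixels = {tuple(p) for p in rng.integers(0, 50, size=(rng.integers(1, 40), 2))}
            cols = sorted(rng.choice(50, size=rng.integers(1, 20), replace=False))
            path = CentroidPath(
                tuple((int(rng.integers(0, 50)), int(c)) for c in cols), "horizontal"
            )
            ref = make_mask(ref_pixels)
            brute = np.mean(
                [
                    min(math.dist(a, b) for b in ref_pixels)
                    for a in path.points
                ]
            )
            assert mmed(path, ref) == pytest.approx(brute, abs=1e-9)

    def test_translating_further_never_decreases(self, make_mask):
        ref = make_mask({(25, c) for c in range(10, 40)})
        previous = -1.0
        for shift in (5, 10, 15, 20):
            path = CentroidPath(tuple((25 - shift, c) for c in range(10, 40)), "horizontal")
            value = mmed(path, ref)
            assert value >= previous
            previous = value


class TestNormalizeMmed:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, 1.0), (5.0, 0.95), (99.9999, pytest.approx(0.0, abs=1e-5)),
         (100.0, 0.0), (150.0, 0.0)],
    )
    def test_values(self, value, expected):
        assert normalize_mmed(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_mmed(-1.0)

    @given(st.floats(0, 300), st.floats(0, 300))
    def test_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert normalize_mmed(lo) >= normalize_mmed(hi)

    def test_custom_threshold(self):
        assert normalize_mmed(25.0, threshold=50.0) == 0.5
        assert normalize_mmed(50.0, threshold=50.0) == 0.0


class TestSiss:
    @pytest.mark.parametrize(
        "d, mn, expected", [(1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (0.5, 0.95, 0.725)]
    )
    def test_arithmetic_mean(self, d, mn, expected):
        assert siss(d, mn) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            siss(1.2, 0.5)


class TestScorePair:
    def test_identity_pair_is_perfect(self, make_mask):
        curve = make_mask({(10 + c // 5, c) for c in range(20)})
        score = score_pair(curve, curve)
        assert score.dice == 1.0
        assert score.mmed == 0.0
        assert score.mmedn == 1.0
        assert score.siss == 1.0
        assert not score.saturated

    def test_far_translation_saturates_to_zero(self, make_mask):
        drawing = make_mask({(5, c) for c in range(10)}, shape=(200, 200))
        reference = make_mask({(155, c) for c in range(10)}, shape=(200, 200))
        score = score_pair(drawing, reference)
        assert score.dice == 0.0
        assert score.saturated
        assert score.mmedn == 0.0
        assert score.siss == 0.0

    def test_thin_stroke_two_px_from_wide_reference(self, make_mask):
        drawing = make_mask({(10, c) for c in range(20)})
        reference = make_mask({(r, c) for r in (12, 13, 14) for c in range(20)})
        score = score_pair(drawing, reference)
        assert score.dice == 0.0
        assert score.mmed == pytest.approx(2.0)
        assert score.mmedn == pytest.approx(0.98)
        assert score.siss == pytest.approx(0.49)

    def test_view_mismatch_rejected(self, make_mask):
        a = make_mask({(1, 1)})
        b = make_mask({(1, 1)}, view="anterior")
        with pytest.raises(ValueError, match="view"):
            score_pair(a, b)

    def test_siss_bounded_by_half_plus_half_dice(self, make_mask):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = make_mask({tuple(p) for p in rng.integers(0, 50, size=(30, 2))})
            b = make_mask({tuple(p) for p in rng.integers(0, 50, size=(30, 2))})
            score = score_pair(a, b)
            assert score.siss <= 0.5 + score.dice / 2 + 1e-12


class TestSimilarityScoreInvariants:
    def test_saturated_requires_zero_mmedn(self):
        with pytest.raises(ValueError, match="saturated"):
            SimilarityScore(dice=0.0, mmed=120.0, mmedn=0.5, siss=0.25, saturated=True)

    def test_siss_consistency_enforced(self):
        with pytest.raises(ValueError, match="siss"):
            SimilarityScore(dice=0.4, mmed=10.0, mmedn=0.9, siss=0.9, saturated=False)
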