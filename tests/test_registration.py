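"""Feature detection, matching, MSAC fitting, and pairwise registration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist

from gridstitch import (
    DetectorConfig,
    MsacConfig,
    Tile,
    Translation,
    detect_features,
    estimate_translation_msac,
    filter_translation,
    match_features,
    register_pair,
    translation_bounds,
)
from gridstitch.registration import NORTH, WEST

from conftest import brute_force_msac, make_link


# ---------------------------------------------------------------------------
# detect_features
# ---------------------------------------------------------------------------

class TestDetectFeatures:
    def test_uniform_region_yields_empty_set(self):
        fs = detect_features(np.zeros((64, 64)), response_threshold=0.0)
        assert len(fs) == 0

    def test_responses_above_threshold_and_offset_applied(self, texture):
        region = texture[:80, 100:220]
        fs = detect_features(region, response_threshold=1000.0, region_offset=(100, 0))
        assert len(fs) > 0
        assert np.all(fs.responses >= 1000.0)
        # tile-local coordinates: x shifted into [100, 220), y in [0, 80)
        assert np.all(fs.keypoints[:, 0] >= 100) and np.all(fs.keypoints[:, 0] < 220)
        assert np.all(fs.keypoints[:, 1] >= 0) and np.all(fs.keypoints[:, 1] < 80)

    def test_higher_threshold_keeps_subset(self, texture):
        lo = detect_features(texture[:120, :120], response_threshold=500.0)
        hi = detect_features(texture[:120, :120], response_threshold=5000.0)
        assert len(hi) < len(lo)
        assert np.all(hi.responses >= 5000.0)

    def test_deterministic(self, texture):
        a = detect_features(texture[:100, :100], 1000.0)
        b = detect_features(texture[:100, :100], 1000.0)
        np.testing.assert_array_equal(a.keypoints, b.keypoints)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_features(np.zeros((10, 10)), -1.0)


# ---------------------------------------------------------------------------
# match_features
# ---------------------------------------------------------------------------

class TestMatchFeatures:
    def test_self_match_is_identity(self, texture):
        fs = detect_features(texture[:150, :150], 1000.0)
        assert len(fs) > 5
        pairs = match_features(fs, fs)
        assert len(pairs) == len(fs)
        np.testing.assert_allclose(pairs[:, 0, :], pairs[:, 1, :])

    def test_empty_set_gives_no_matches(self, texture):
        fs = detect_features(texture[:100, :100], 1000.0)
        empty = detect_features(np.zeros((32, 32)), 0.0)
        assert len(match_features(fs, empty)) == 0
        assert len(match_features(empty, fs)) == 0

    def test_keypoints_matched_at_most_once(self, texture):
        a = detect_features(texture[:200, :40], 1000.0)
        b = detect_features(texture[:200, 10:50], 1000.0)
        pairs = match_features(a, b)
        for side in (0, 1):
            pts = [tuple(p) for p in pairs[:, side, :]]
            assert len(pts) == len(set(pts))

    def test_known_shift_consistency_against_distance_matrix_oracle(self, texture):
        """Strips cut from one image with a known shift: at least 80% of the
        returned matches agree with the true displacement, and the matcher's
        pairing never beats an exhaustive descriptor-distance check."""
        shift = 9
        a = detect_features(texture[:, 300:340], 1000.0)
        b = detect_features(texture[:, 300 + shift: 340 + shift], 1000.0)
        pairs = match_features(a, b)
        assert len(pairs) >= 5
        disp = pairs[:, 0, :] - pairs[:, 1, :]
        good = np.sum(
            (np.abs(disp[:, 0] - shift) < 1.0) & (np.abs(disp[:, 1]) < 1.0)
        )
        assert good / len(pairs) >= 0.8
        # oracle: each returned pair must be a mutual nearest neighbor of the
        # full descriptor-distance matrix
        d = cdist(a.descriptors, b.descriptors)
        kp_a = {tuple(k): i for i, k in enumerate(a.keypoints)}
        kp_b = {tuple(k): j for j, k in enumerate(b.keypoints)}
        for pa, pb in pairs:
            i, j = kp_a[tuple(pa)], kp_b[tuple(pb)]
            assert d[i, j] == d[i, :].min()
            assert d[i, j] == d[:, j].min()


# ---------------------------------------------------------------------------
# estimate_translation_msac
# ---------------------------------------------------------------------------

def _corr_from_disp(disp, rng):
    """Build correspondences with given displacements at random ref points."""
    ref = rng.uniform(0, 500, size=(len(disp), 2))
    return np.stack([ref, ref - disp], axis=1)


class TestMsac:
    def test_noiseless_consensus(self):
        rng = np.random.default_rng(0)
        disp = np.tile([300.0, 2.0], (10, 1))
        res = estimate_translation_msac(_corr_from_disp(disp, rng))
        assert res is not None
        t, n_in = res
        assert (t.t_x, t.t_y) == (300.0, 2.0)
        assert n_in == 10

    def test_outlier_rejection_matches_bruteforce_optimum(self):
        rng = np.random.default_rng(1)
        inl = np.tile([300.0, 2.0], (20, 1)) + rng.uniform(-0.3, 0.3, (20, 2))
        out = rng.uniform(-50, 50, (5, 2))
        corr = _corr_from_disp(np.vstack([inl, out]), rng)
        res = estimate_translation_msac(corr, inlier_tol=2.0, full_output=True)
        assert res is not None
        t, n_in, _, score = res
        assert n_in >= 20
        assert abs(t.t_x - 300.0) < 0.5 and abs(t.t_y - 2.0) < 0.5
        # the selected hypothesis attains the brute-force truncated-loss optimum
        _, best_score = brute_force_msac(corr, 2.0)
        assert score == pytest.approx(best_score)

    def test_below_match_floor_returns_not_found(self):
        rng = np.random.default_rng(2)
        corr = _corr_from_disp(np.tile([10.0, 0.0], (2, 1)), rng)
        assert estimate_translation_msac(corr, min_matches=3) is None

    def test_too_few_inliers_returns_not_found(self):
        rng = np.random.default_rng(3)
        disp = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0], [300.0, 0.0]])
        assert (
            estimate_translation_msac(_corr_from_disp(disp, rng), inlier_tol=2.0)
            is None
        )

    @given(st.integers(0, 10_000))
    def test_score_equals_bruteforce_on_random_sets(self, seed):
        """MSAC's selected score equals the exhaustive single-hypothesis
        optimum for problems of at most 50 correspondences."""
        rng = np.random.default_rng(seed)
        n_in = int(rng.integers(3, 40))
        n_out = int(rng.integers(0, 11))
        center = rng.uniform(-200, 200, 2)
        disp = np.vstack([
            center + rng.normal(0, 0.5, (n_in, 2)),
            rng.uniform(-300, 300, (n_out, 2)),
        ])
        corr = _corr_from_disp(disp, rng)
        _, oracle_score = brute_force_msac(corr, 2.0)
        res = estimate_translation_msac(
            corr, inlier_tol=2.0, min_inliers=1, min_matches=3, full_output=True
        )
        assert res is not None
        _, _, _, score = res
        assert score == pytest.approx(oracle_score)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            estimate_translation_msac(np.zeros((5, 2, 2)), inlier_tol=0.0)


# ---------------------------------------------------------------------------
# filter_translation (stage-model filter)
# ---------------------------------------------------------------------------

class TestStageFilter:
    W, H, o = 1000, 800, 0.25

    def check(self, direction, t, expect_valid):
        link = make_link(direction, t=t, n_matched=12.0, stage="strip")
        out = filter_translation(link, self.W, self.H, self.o)
        assert out.is_valid == expect_valid
        if not expect_valid:
            assert not out.translation.is_finite
            assert np.isnan(out.n_matched)

    @pytest.mark.parametrize(
        "t, valid",
        [
            ((750.0, 0.0), True),     # center of range
            ((730.0, 0.0), True),     # exactly at -2% boundary
            ((770.0, 0.0), True),     # exactly at +2% boundary
            ((729.99, 0.0), False),   # just below
            ((770.01, 0.0), False),   # just above
            ((750.0, 16.0), True),    # t_y at +2% of H
            ((750.0, -16.0), True),
            ((750.0, 16.01), False),
            ((700.0, 0.0), False),
        ],
    )
    def test_west_boundaries(self, t, valid):
        self.check(WEST, t, valid)

    @pytest.mark.parametrize(
        "t, valid",
        [
            ((0.0, 600.0), True),
            ((0.0, 584.0), True),     # exactly H(1-o) - 0.02 H
            ((0.0, 616.0), True),
            ((0.0, 583.9), False),
            ((20.0, 600.0), True),    # exactly +2% of W
            ((20.1, 600.0), False),
        ],
    )
    def test_north_boundaries(self, t, valid):
        self.check(NORTH, t, valid)

    def test_invalid_link_passes_through(self):
        link = make_link(WEST)
        assert filter_translation(link, self.W, self.H, self.o) is link

    @given(
        st.floats(600, 900),
        st.floats(-30, 30),
    )
    def test_validity_matches_interval_arithmetic(self, tx, ty):
        (xl, xh), (yl, yh) = translation_bounds(WEST, self.W, self.H, self.o)
        link = make_link(WEST, t=(tx, ty), n_matched=5.0)
        out = filter_translation(link, self.W, self.H, self.o)
        assert out.is_valid == (xl <= tx <= xh and yl <= ty <= yh)


# ---------------------------------------------------------------------------
# register_pair
# ---------------------------------------------------------------------------

class TestRegisterPair:
    @pytest.mark.parametrize("overlap", [0.10, 0.25, 0.30])
    def test_recovers_crop_offset_from_strip(self, texture, overlap):
        """Two tiles cropped from one textured image: the recovered
        translation equals the crop offset within 1 px, from the strip."""
        W = 200
        tx = round(W * (1 - overlap))
        ref = Tile(row=0, col=0, pixels=texture[50:50 + W, 10:10 + W])
        mov = Tile(row=0, col=1, pixels=texture[50:50 + W, 10 + tx:10 + tx + W])
        link = register_pair(ref, mov, WEST, overlap_fraction=overlap)
        assert link.is_valid
        assert link.stage_used == "strip"
        assert abs(link.translation.t_x - tx) <= 1.0
        assert abs(link.translation.t_y) <= 1.0
        assert link.n_matched >= 3

    def test_north_direction(self, texture):
        H = 200
        ty = 150
        ref = Tile(row=0, col=0, pixels=texture[10:10 + H, 50:250])
        mov = Tile(row=1, col=0, pixels=texture[10 + ty:10 + ty + H, 50:250])
        link = register_pair(ref, mov, NORTH, overlap_fraction=0.25)
        assert link.is_valid
        assert abs(link.translation.t_y - ty) <= 1.0
        assert abs(link.translation.t_x) <= 1.0

    def test_uniform_overlap_gives_invalid_sentinel(self, texture):
        W = 200
        ref = Tile(row=0, col=0, pixels=texture[:W, :W])
        mov = Tile(row=0, col=1, pixels=np.full((W, W), 128, dtype=np.uint8))
        link = register_pair(ref, mov, WEST, overlap_fraction=0.25)
        assert not link.is_valid
        assert not link.translation.is_finite
        assert np.isnan(link.n_matched)
        assert link.stage_used is None

    def test_mismatched_shapes_raise(self, texture):
        ref = Tile(row=0, col=0, pixels=texture[:200, :200])
        mov = Tile(row=0, col=1, pixels=texture[:100, :100])
        with pytest.raises(ValueError, match="grid inconsistency"):
            register_pair(ref, mov, WEST, overlap_fraction=0.25)

    def test_strip_and_full_overlap_stages_agree(self, tile_pair):
        ref, mov, (tx, ty) = tile_pair
        strip = register_pair(ref, mov, WEST, 0.25, stages=("strip",))
        full = register_pair(ref, mov, WEST, 0.25, stages=("full_overlap",))
        assert strip.is_valid and full.is_valid
        assert abs(strip.translation.t_x - full.translation.t_x) <= 1.0
        assert abs(strip.translation.t_y - full.translation.t_y) <= 1.0
        assert abs(full.translation.t_x - tx) <= 1.0

    def test_shading_changes_translation_less_than_a_pixel(self, tile_pair):
        """A +-30% multiplicative flat-field applied to both tiles moves the
        recovered translation by less than 1 px (brightness robustness)."""
        ref, mov, _ = tile_pair
        base = register_pair(ref, mov, WEST, 0.25)
        H, W = ref.shape
        yy, xx = np.mgrid[0:H, 0:W]
        cy, cx = (H - 1) / 2, (W - 1) / 2
        gain = 1.0 - 0.3 * (((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2) / 2
        shade = lambda t: Tile(
            row=t.row, col=t.col,
            pixels=np.clip(t.pixels * gain, 0, 255).astype(np.uint8),
        )
        shaded = register_pair(shade(ref), shade(mov), WEST, 0.25)
        assert shaded.is_valid
        assert abs(shaded.translation.t_x - base.translation.t_x) < 1.0
        assert abs(shaded.translation.t_y - base.translation.t_y) < 1.0

    def test_deterministic_given_seed(self, tile_pair):
        ref, mov, _ = tile_pair
        a = register_pair(ref, mov, WEST, 0.25, seed=42)
        b = register_pair(ref, mov, WEST, 0.25, seed=42)
        assert a.translation == b.translation
        assert a.n_matched == b.n_matched

    def test_default_strip_fraction_is_five_percent(self):
        import inspect

        sig = inspect.signature(register_pair)
        assert sig.parameters["strip_fraction"].default == 0.05
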