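"""Posture/kinematic features vs brute-force oracles, plus range,
scale- and rotation-invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethome.features import (
    FRAME_FEATURES,
    aggregate_action_features,
    bend_angle_deg,
    compute_frame_features,
    length_ratio,
    shape_factor,
    spine_order_parameter,
    velocity_segment_cosine,
    velocity_spine_projection,
)
from ethome.io import Track


def _random_spine(rng, K=11):
    # random walk with non-degenerate steps
    steps = rng.normal(0, 1, (K - 1, 2)) + [0.5, 0.0]
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


# ---------------------------------------------------------------------------
# spine order parameter


class TestOrderParameter:
    def test_straight_spine_gives_one(self):
        pts = np.stack([np.linspace(0, 4, 6), np.zeros(6)], axis=1)
        assert spine_order_parameter(pts, [1.0, 0.0]) == pytest.approx(1.0)

    def test_perpendicular_segments_give_minus_half(self):
        pts = np.stack([np.zeros(5), np.linspace(0, 2, 5)], axis=1)
        assert spine_order_parameter(pts, [1.0, 0.0]) == pytest.approx(-0.5)

    def test_mixed_cosines_closed_form(self):
        # segments with cosθ = 1, 0.5, 0 vs the x-axis → ⟨cos²⟩ = 5/12, S = 0.125
        dirs = np.array(
            [[1.0, 0.0], [0.5, np.sqrt(3) / 2], [0.0, 1.0]]
        )
        pts = np.vstack([[0.0, 0.0], np.cumsum(dirs, axis=0)])
        assert spine_order_parameter(pts, [1.0, 0.0]) == pytest.approx(0.125, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        axis = np.array([0.3, 0.7])
        for _ in range(50):
            pts = _random_spine(rng)
            segs = np.diff(pts, axis=0)
            u = axis / np.linalg.norm(axis)
            cos = [s @ u / np.linalg.norm(s) for s in segs]
            expect = 0.5 * (3 * np.mean(np.square(cos)) - 1)
            assert spine_order_parameter(pts, axis) == pytest.approx(expect, abs=1e-12)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            spine_order_parameter(np.zeros((3, 2)) + np.arange(3)[:, None], [0, 0])


class TestShapeFactor:
    def test_isotropic_gives_zero(self):
        assert shape_factor(np.eye(2) * 2.5) == 0.0

    def test_rank_one_gives_one(self):
        v = np.array([1.0, 2.0])
        assert shape_factor(np.outer(v, v)) == pytest.approx(1.0)

    def test_eigenvalues_three_and_one(self):
        assert shape_factor(np.diag([3.0, 1.0])) == pytest.approx(0.5)

    def test_degenerate_zero_covariance(self):
        assert shape_factor(np.zeros((2, 2))) == 0.0

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            shape_factor(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestLengthRatio:
    def test_mirror_symmetric_spine_is_one(self):
        pts = np.array([[-2, 0], [-1, 0.5], [0, 0.8], [1, 0.5], [2, 0]], dtype=float)
        assert length_ratio(pts) == pytest.approx(1.0)

    def test_simple_arithmetic(self):
        pts = np.array([[2.0, 0.0], [-2.0, 3.0], [-1.0, -3.0]])
        g = pts.mean(axis=0)
        expect = np.linalg.norm(pts[0] - g) / np.linalg.norm(pts[-1] - g)
        assert length_ratio(pts) == pytest.approx(expect, abs=1e-12)

    def test_random_spines_match_distance_oracle(self, rng):
        for _ in range(50):
            pts = _random_spine(rng, K=7)
            g = pts.mean(axis=0)
            expect = np.sqrt(((pts[0] - g) ** 2).sum()) / np.sqrt(((pts[-1] - g) ** 2).sum())
            assert length_ratio(pts) == pytest.approx(expect, abs=1e-12)


def _projection_oracle(v, pts, end):
    """Exhaustive min-distance segment search + dot product."""
    anchor = pts[0] if end == "head" else pts[-1]
    target = anchor + v
    best, best_d = None, np.inf
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        s = np.clip((target - a) @ ab / (ab @ ab), 0, 1)
        d = np.linalg.norm(target - (a + s * ab))
        if d < best_d:
            best_d, best = d, ab
    length = sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:]))
    return (v @ best / np.linalg.norm(best)) / length


class TestVelocityProjection:
    def test_velocity_along_first_segment_signed_toward_tail(self):
        # head at x=0, tail at x=4: head→tail direction is +x
        pts = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
        toward_tail = np.array([0.5, 0.0])
        assert velocity_spine_projection(toward_tail, pts, end="head") == pytest.approx(
            0.5 / 4.0
        )
        assert velocity_spine_projection(-toward_tail, pts, end="head") == pytest.approx(
            -0.5 / 4.0
        )

    def test_perpendicular_velocity_has_zero_component(self):
        pts = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
        v = np.array([0.0, 0.3])
        assert velocity_spine_projection(v, pts, end="head") == pytest.approx(0.0, abs=1e-12)
        assert velocity_spine_projection(v, pts, end="head", mode="residual") == pytest.approx(
            0.3 / 4.0
        )

    def test_bent_spine_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            pts = _random_spine(rng, K=9)
            v = rng.normal(0, 0.5, 2)
            for end in ("head", "tail"):
                assert velocity_spine_projection(v, pts, end=end) == pytest.approx(
                    _projection_oracle(v, pts, end), abs=1e-12
                )


class TestVelocityCosine:
    @pytest.mark.parametrize(
        "v,seg,expect",
        [
            ([1.0, 1.0], [2.0, 2.0], 1.0),
            ([1.0, 0.0], [-3.0, 0.0], -1.0),
            ([0.0, 1.0], [1.0, 0.0], 0.0),
        ],
    )
    def test_reference_angles(self, v, seg, expect):
        assert velocity_segment_cosine(v, seg) == pytest.approx(expect, abs=1e-12)

    def test_zero_vector_gives_nan(self):
        assert np.isnan(velocity_segment_cosine([0.0, 0.0], [1.0, 0.0]))


# ---------------------------------------------------------------------------
# per-frame series


def _track_from_points(pts_series, dt=0.1):
    n = len(pts_series)
    return Track(
        larva_id="x",
        t=np.arange(n) * dt,
        points=np.asarray(pts_series, dtype=float),
        valid=np.ones(n, dtype=bool),
    )


def test_stationary_larva_all_speeds_zero():
    pts = np.stack([np.linspace(0, 4, 11), np.zeros(11)], axis=1)
    track = _track_from_points([pts] * 10)
    df = compute_frame_features(track)
    for col in ("v_head", "v_motion", "v_tail"):
        np.testing.assert_allclose(df[col], 0.0, atol=1e-12)
    assert df["S"].nunique() == 1


def test_rigid_translation_normalized_speeds():
    pts = np.stack([np.linspace(0, 4, 11), np.zeros(11)], axis=1)
    speed = 0.8  # mm/s along +x
    frames = [pts + [speed * i * 0.1, 0.0] for i in range(10)]
    df = compute_frame_features(_track_from_points(frames))
    for col in ("v_head", "v_motion", "v_tail"):
        np.testing.assert_allclose(df[col], speed / 4.0, atol=1e-9)
    # head leads: spine runs head→tail along +x means head at x=0 … here head
    # is the first point at x=0, so motion along +x is tail-ward (backward)
    np.testing.assert_allclose(np.abs(df["v_forward"]), speed / 4.0, atol=1e-9)


def test_scale_invariance_of_normalized_features(rng):
    pts0 = _random_spine(rng, K=11)
    frames = [pts0 + rng.normal(0, 0.05, pts0.shape) for _ in range(12)]
    track = _track_from_points(frames)
    scaled = _track_from_points([3.7 * f for f in frames])
    a = compute_frame_features(track)
    b = compute_frame_features(scaled)
    for col in FRAME_FEATURES:
        np.testing.assert_allclose(a[col], b[col], atol=1e-9, err_msg=col)


def test_rotation_invariance_of_normalized_features(rng):
    th = 1.1
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts0 = _random_spine(rng, K=11)
    frames = [pts0 + rng.normal(0, 0.05, pts0.shape) for _ in range(12)]
    a = compute_frame_features(_track_from_points(frames))
    b = compute_frame_features(_track_from_points([f @ R.T for f in frames]))
    for col in FRAME_FEATURES:
        np.testing.assert_allclose(a[col], b[col], atol=1e-9, err_msg=col)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_range_invariants_on_random_postures(seed):
    rng = np.random.default_rng(seed)
    frames = [_random_spine(rng, K=7) for _ in range(8)]
    df = compute_frame_features(_track_from_points(frames))
    assert df["S"].between(-0.5 - 1e-12, 1 + 1e-12).all()
    assert df["lam"].dropna().between(0, 1).all()
    assert (df["len_ratio"] > 0).all()
    assert df["cos_head"].dropna().between(-1, 1).all()
    assert df["cos_tail"].dropna().between(-1, 1).all()


# ---------------------------------------------------------------------------
# aggregates


class _Iv:
    def __init__(self, start, end):
        self.start, self.end = start, end


def test_aggregate_constant_feature():
    pts = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
    df = compute_frame_features(_track_from_points([pts] * 20))
    agg = aggregate_action_features(df, _Iv(0.5, 1.5))
    assert agg["S_mean"] == agg["S_max"] == agg["S_min"] == pytest.approx(1.0)
    assert agg["duration"] == pytest.approx(1.0)
    assert not agg["pre_truncated"] and not agg["post_truncated"]


def test_aggregate_min_mean_max_ordering(rng):
    pts = [_random_spine(rng) for _ in range(30)]
    df = compute_frame_features(_track_from_points(pts))
    agg = aggregate_action_features(df, _Iv(0.3, 2.4))
    for f in FRAME_FEATURES:
        if np.isnan(agg[f + "_mean"]):
            continue
        assert agg[f + "_min"] <= agg[f + "_mean"] + 1e-12
        assert agg[f + "_mean"] <= agg[f + "_max"] + 1e-12


def test_aggregate_frame_index_example():
    # a feature equal to the frame index over 4 frames {0,1,2,3}
    pts = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
    df = compute_frame_features(_track_from_points([pts] * 4))
    df["rel_length"] = np.arange(4.0)
    agg = aggregate_action_features(df, _Iv(0.0, 0.4))
    assert agg["rel_length_mean"] == pytest.approx(1.5)
    assert agg["rel_length_max"] == 3 and agg["rel_length_min"] == 0


def test_aggregate_truncation_flag_at_track_start():
    pts = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
    df = compute_frame_features(_track_from_points([pts] * 20))
    agg = aggregate_action_features(df, _Iv(0.0, 0.5))
    assert agg["pre_truncated"] and not agg["post_truncated"]


def test_aggregate_empty_interval_rejected():
    pts = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
    df = compute_frame_features(_track_from_points([pts] * 5))
    with pytest.raises(ValueError, match="empty interval"):
        aggregate_action_features(df, _Iv(10.0, 11.0))


def test_bend_angle_straight_and_right_angle():
    straight = np.stack([np.linspace(0, 4, 5), np.zeros(5)], axis=1)
    assert bend_angle_deg(straight) == pytest.approx(0.0, abs=1e-9)
    bent = np.array([[0.0, 2.0], [0.0, 1.0], [0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    assert bend_angle_deg(bent) > 30
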