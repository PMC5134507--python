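import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modicovi._util import wrap_angle
from modicovi.edge_extraction import EdgeSegment
from modicovi.pair_geometry import (
    PAIR_AXES,
    enumerate_pairs,
    fingerprint,
    pair_array,
    pair_features,
    relative_pose,
)


def circle_segments(radius, n=24, center=(0.0, 0.0), tangent=True):
    """Segments placed analytically on a circle, oriented tangentially."""
    out = []
    for i in range(n):
        phi = 2 * np.pi * i / n
        theta = phi + np.pi / 2 if tangent else phi
        out.append(
            EdgeSegment(
                x=center[0] + radius * np.cos(phi),
                y=center[1] + radius * np.sin(phi),
                theta=wrap_angle(theta),
            )
        )
    return out


class TestRelativePose:
    def test_identical_segments_have_zero_pose(self):
        p = EdgeSegment(5, 7, 1.2)
        assert relative_pose(p, p) == (0.0, 0.0, 0.0)

    def test_aligned_frame_is_world_offset(self):
        pose = relative_pose(EdgeSegment(0, 0, 0.0), EdgeSegment(3, 4, np.pi / 2))
        assert pose[0] == pytest.approx(3)
        assert pose[1] == pytest.approx(4)
        assert pose[2] == pytest.approx(np.pi / 2)

    def test_matches_rotation_matrix_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x1, y1, x2, y2 = rng.uniform(-50, 50, 4)
            t1, t2 = rng.uniform(-np.pi, np.pi, 2)
            dx, dy, dt = relative_pose(EdgeSegment(x1, y1, t1), EdgeSegment(x2, y2, t2))
            rot = np.array([[math.cos(-t1), -math.sin(-t1)], [math.sin(-t1), math.cos(-t1)]])
            expected = rot @ np.array([x2 - x1, y2 - y1])
            assert dx == pytest.approx(expected[0], abs=1e-9)
            assert dy == pytest.approx(expected[1], abs=1e-9)
            assert dt == pytest.approx(wrap_angle(t2 - t1), abs=1e-12)


class TestPairFeatures:
    def test_parallel_segments_have_zero_curvature(self):
        d, k = pair_features(6.0, 8.0, 0.0)
        assert d == pytest.approx(10.0)
        assert k == 0.0

    def test_opposed_segments(self):
        d, k = pair_features(2.0, 0.0, np.pi)
        assert (d, k) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            pair_features(0.0, 0.0, 1.0)

    @pytest.mark.parametrize("radius", [5.0, 20.0, 80.0])
    def test_circle_curvature_equals_inverse_radius(self, radius):
        # chord d = 2 r sin(phi/2) and sqrt(2 - 2 cos phi) = 2 sin(phi/2)
        segs = circle_segments(radius, n=36, center=(3.0, -7.0))
        for p in enumerate_pairs(segs, max_dist=2 * radius + 1):
            assert p.k == pytest.approx(1.0 / radius, abs=1e-9)


class TestEnumeratePairs:
    def test_fewer_than_two_segments_yield_nothing(self):
        assert enumerate_pairs([]) == []
        assert enumerate_pairs([EdgeSegment(0, 0, 0)]) == []

    def test_collinear_cutoff_counting(self):
        segs = [EdgeSegment(0, 0, 0), EdgeSegment(100, 0, 0), EdgeSegment(200, 0, 0)]
        pairs = enumerate_pairs(segs, max_dist=125)
        assert len(pairs) == 4  # the two 200-px ordered pairs are excluded
        assert all(p.d == pytest.approx(100) for p in pairs)

    def test_cutoff_is_strict(self):
        segs = [EdgeSegment(0, 0, 0), EdgeSegment(125, 0, 0)]
        assert enumerate_pairs(segs, max_dist=125) == []

    def test_coincident_segments_dropped(self):
        segs = [EdgeSegment(0, 0, 0.0), EdgeSegment(0, 0, 1.0), EdgeSegment(5, 0, 0.5)]
        pairs = enumerate_pairs(segs, max_dist=50)
        assert len(pairs) == 4
        assert all(p.d > 0 for p in pairs)

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(3)
        segs = [
            EdgeSegment(x, y, t)
            for x, y, t in zip(
                rng.uniform(0, 300, 50), rng.uniform(0, 300, 50), rng.uniform(-np.pi, np.pi, 50)
            )
        ]
        got = {
            (round(p.dx, 6), round(p.dy, 6), round(p.dtheta, 6)) for p in enumerate_pairs(segs)
        }
        expected = set()
        for i, a in enumerate(segs):
            for j, b in enumerate(segs):
                if i == j:
                    continue
                if math.hypot(b.x - a.x, b.y - a.y) < 125:
                    dx, dy, dt = relative_pose(a, b)
                    expected.add((round(dx, 6), round(dy, 6), round(dt, 6)))
        assert got == expected


class TestInvariants:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-200, 200),
        ty=st.floats(-200, 200),
        seed=st.integers(0, 50),
    )
    def test_rigid_motion_invariance(self, angle, tx, ty, seed):
        rng = np.random.default_rng(seed)
        xs, ys = rng.uniform(0, 200, 12), rng.uniform(0, 200, 12)
        ts = rng.uniform(-np.pi, np.pi, 12)
        segs = [EdgeSegment(x, y, t) for x, y, t in zip(xs, ys, ts)]
        c, s = math.cos(angle), math.sin(angle)
        moved = [
            EdgeSegment(c * x - s * y + tx, s * x + c * y + ty, wrap_angle(t + angle))
            for x, y, t in zip(xs, ys, ts)
        ]
        a, b = pair_array(segs), pair_array(moved)
        assert a.shape == b.shape

        def embed(arr):
            # angle on the unit circle avoids the wrap discontinuity when
            # matching rows between the two enumerations
            return np.column_stack(
                [arr[:, 0], arr[:, 1], np.cos(arr[:, 2]), np.sin(arr[:, 2]), arr[:, 3], arr[:, 4]]
            )

        from scipy.spatial import cKDTree

        dist, _ = cKDTree(embed(b)).query(embed(a))
        assert dist.max() < 1e-9

    def test_swapping_order_negates_dtheta_preserves_d_and_k(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = EdgeSegment(*rng.uniform(0, 80, 2), rng.uniform(-np.pi, np.pi))
            b = EdgeSegment(*rng.uniform(0, 80, 2), rng.uniform(-np.pi, np.pi))
            fwd = relative_pose(a, b)
            rev = relative_pose(b, a)
            assert abs(wrap_angle(fwd[2] + rev[2])) < 1e-9
            df, kf = pair_features(*fwd)
            dr, kr = pair_features(*rev)
            assert df == pytest.approx(dr, abs=1e-9)
            assert kf == pytest.approx(kr, abs=1e-9)


class TestFingerprint:
    def test_empty_pairs_all_zero(self):
        fp = fingerprint(np.empty((0, 5)), axes=("dx", "dtheta"), bins=8)
        assert fp.counts.sum() == 0

    def test_counts_conserved(self):
        rng = np.random.default_rng(9)
        pairs = rng.uniform(-1, 1, size=(40, 5))
        fp = fingerprint(pairs, axes=("dx", "dy"), bins=5)
        assert fp.counts.sum() == 40

    def test_identical_axes_rejected(self):
        with pytest.raises(ValueError):
            fingerprint(np.empty((0, 5)), axes=("dx", "dx"))

    def test_parallel_ribbon_mass_concentrates_near_zero_dtheta(self):
        from modicovi.density_model import scene_pairs
        from modicovi.synthetic_scenes import make_monocot

        canvas = np.zeros((256, 256), bool)
        sp = make_monocot(length_px=200, width_px=10, curvature=0.0).mask
        canvas[100 : 100 + sp.shape[0], 20 : 20 + sp.shape[1]] = sp
        pairs = scene_pairs(canvas)
        fp = fingerprint(pairs, axes=("dtheta", "d"), bins=(16, 8),
                         ranges=((-np.pi, np.pi), (0, 125)))
        centers = (fp.x_edges[:-1] + fp.x_edges[1:]) / 2
        near_zero = np.abs(centers) < 0.4
        assert fp.counts[near_zero].sum() > 0.35 * fp.counts.sum()
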