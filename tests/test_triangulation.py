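"""Rectification, motion correction and Linear-Eigen triangulation."""

import numpy as np
import pytest

from diamoco.geometry import make_circular_trajectory, project_point
from diamoco.triangulation import (
    motion_correct,
    rectify_pair,
    triangulate_linear_eigen,
    triangulate_pair,
    triangulate_sequence,
)


@pytest.fixture(scope="module")
def geom():
    return make_circular_trajectory(200)


def _moving_point(t, amplitude=23.0, period=4.0):
    return np.array([50.0, 0.0, -28.0 - amplitude * np.sin(np.pi * t / period) ** 2])


class TestRectification:
    def test_static_points_share_rectified_v(self, geom):
        """Corresponding rectified points of a static scene lie on the same row."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = int(rng.integers(0, 100))
            j = i + int(rng.integers(10, 100))
            pair = rectify_pair(geom.matrices[i], geom.matrices[j])
            X = rng.uniform(-100, 100, size=(100, 3))
            vi = project_point(pair.P_i, X)[:, 1]
            vj = project_point(pair.P_j, X)[:, 1]
            assert np.abs(vi - vj).max() < 1e-6

    def test_transform_consistency_with_new_matrices(self, geom):
        """T maps original projections onto projections of the new cameras."""
        pair = rectify_pair(geom.matrices[10], geom.matrices[100])
        X = np.array([20.0, -30.0, 15.0])
        g = project_point(geom.matrices[10], X)
        assert pair.transform(pair.T_i, g) == pytest.approx(
            project_point(pair.P_i, X), abs=1e-6
        )

    def test_rectifying_a_rectified_pair_is_identity(self, geom):
        pair = rectify_pair(geom.matrices[0], geom.matrices[90])
        again = rectify_pair(pair.P_i, pair.P_j)
        assert np.allclose(again.T_i, np.eye(3), atol=1e-9)
        assert np.allclose(again.T_j, np.eye(3), atol=1e-9)

    def test_coincident_sources_degenerate(self, geom):
        with pytest.raises(ValueError):
            rectify_pair(geom.matrices[5], geom.matrices[5])


class TestMotionCorrect:
    def test_direct_application(self):
        g, gp = motion_correct((10.0, 20.0), (30.0, 25.0))
        assert tuple(gp) == (30.0, 20.0)
        assert tuple(g) == (10.0, 20.0)

    def test_static_pair_untouched(self):
        _, gp = motion_correct((10.0, 20.0), (30.0, 20.0))
        assert tuple(gp) == (30.0, 20.0)

    def test_vertical_disparity_always_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.uniform(0, 500, 2), rng.uniform(0, 500, 2)
            g, gp = motion_correct(a, b)
            assert g[1] == gp[1]


class TestLinearEigen:
    def test_exact_static_point(self, geom):
        X = np.array([30.0, -20.0, 40.0])
        g = project_point(geom.matrices[0], X)
        gp = project_point(geom.matrices[90], X)
        Xr = triangulate_linear_eigen(geom.matrices[0], geom.matrices[90], g, gp)
        assert np.linalg.norm(Xr - X) < 1e-9

    def test_opposed_views_handled_or_flagged_degenerate(self):
        g360 = make_circular_trajectory(181, increment=1.0)
        # off-baseline axis point: the two rays still intersect at a shallow
        # angle and triangulation stays exact
        X = np.array([0.0, 0.0, 10.0])
        g = project_point(g360.matrices[0], X)
        gp = project_point(g360.matrices[180], X)
        Xr = triangulate_linear_eigen(g360.matrices[0], g360.matrices[180], g, gp)
        assert np.linalg.norm(Xr - X) < 1e-6
        # a point on the baseline makes the rays collinear: flagged degenerate
        B = np.array([10.0, 0.0, 0.0])
        g = project_point(g360.matrices[0], B)
        gp = project_point(g360.matrices[180], B)
        with pytest.raises(ValueError):
            triangulate_linear_eigen(g360.matrices[0], g360.matrices[180], g, gp)

    def test_iterative_beats_plain_under_noise(self, geom):
        """Depth reweighting reduces mean 3D error for noisy correspondences."""
        rng = np.random.default_rng(11)
        X = np.array([40.0, 10.0, -30.0])
        P1, P2 = geom.matrices[0], geom.matrices[90]
        g = project_point(P1, X)
        gp = project_point(P2, X)
        e_iter, e_plain = [], []
        for _ in range(100):
            n1, n2 = rng.normal(0, 0.1, 2), rng.normal(0, 0.1, 2)
            e_iter.append(
                np.linalg.norm(triangulate_linear_eigen(P1, P2, g + n1, gp + n2, iterative=True) - X)
            )
            e_plain.append(
                np.linalg.norm(triangulate_linear_eigen(P1, P2, g + n1, gp + n2, iterative=False) - X)
            )
        assert np.mean(e_iter) < np.mean(e_plain)


class TestMotionCorrectedTriangulation:
    def test_pure_si_motion_recovered_exactly(self, geom):
        """The central claim: after rectification, zeroing the vertical
        disparity removes a pure SI displacement between the two acquisition
        times, so the reference-time point is recovered."""
        t_i, t_j = geom.timestamps[20], geom.timestamps[110]
        g = project_point(geom.matrices[20], _moving_point(t_i))
        gp = project_point(geom.matrices[110], _moving_point(t_j))
        X = triangulate_pair(geom.matrices[20], geom.matrices[110], g, gp)
        assert np.linalg.norm(X - _moving_point(t_i)) < 0.05

    def test_standard_mode_is_an_order_of_magnitude_worse(self, geom):
        t_i, t_j = geom.timestamps[0], geom.timestamps[90]
        g = project_point(geom.matrices[0], _moving_point(t_i))
        gp = project_point(geom.matrices[90], _moving_point(t_j))
        Xc = triangulate_pair(geom.matrices[0], geom.matrices[90], g, gp, mode="rectified_corrected")
        Xs = triangulate_pair(geom.matrices[0], geom.matrices[90], g, gp, mode="standard")
        ec = np.linalg.norm(Xc - _moving_point(t_i))
        es = np.linalg.norm(Xs - _moving_point(t_i))
        assert es > 10 * ec

    def test_offset_direction_symmetry(self, geom):
        """Mean error with partner +k matches partner -k to within 2x.

        Exact correspondences triangulate to machine precision, where ratios
        are meaningless; a small seeded detector noise gives a stable scale.
        """
        rng = np.random.default_rng(21)
        errs = {}
        for j in (190, 10):
            i = 100
            g0 = project_point(geom.matrices[i], _moving_point(geom.timestamps[i]))
            gp0 = project_point(geom.matrices[j], _moving_point(geom.timestamps[j]))
            trial = []
            for _ in range(50):
                X = triangulate_pair(
                    geom.matrices[i], geom.matrices[j],
                    g0 + rng.normal(0, 0.1, 2), gp0 + rng.normal(0, 0.1, 2),
                )
                trial.append(np.linalg.norm(X - _moving_point(geom.timestamps[i])))
            errs[j] = np.mean(trial)
        ratio = max(errs[190] / errs[10], errs[10] / errs[190])
        assert ratio < 2.0


class TestTriangulateSequence:
    def test_static_scene_exact_for_all_modes_and_offsets(self, geom):
        X = np.array([50.0, 0.0, -28.0])
        vertices = np.asarray([project_point(P, X) for P in geom.matrices])
        for mode in ("rectified_corrected", "standard"):
            for off in (10.0, 30.0, 90.0):
                pts, partners = triangulate_sequence(vertices, geom, offset_deg=off, mode=mode)
                assert np.abs(pts - X).max() < 1e-6
                assert len(partners) == geom.n_views

    def test_end_of_scan_pairs_backwards(self, geom):
        X = np.array([50.0, 0.0, -28.0])
        vertices = np.asarray([project_point(P, X) for P in geom.matrices])
        _, partners = triangulate_sequence(vertices, geom, offset_deg=90.0)
        assert partners[0] == 90
        assert partners[150] == 60  # 150 + 90 >= 200, falls back to i - k

    def test_unrepresentable_offset_rejected(self, geom):
        vertices = np.zeros((geom.n_views, 2))
        with pytest.raises(ValueError):
            triangulate_sequence(vertices, geom, offset_deg=500.0)
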