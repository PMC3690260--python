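"""Diaphragm-contour tracking: ROIs, edge extraction, RANSAC, constraints."""

import numpy as np
import pytest

from diamoco.simulator import Ellipsoid, PhantomSpec, forward_project
from diamoco.geometry import DetectorSpec, make_circular_trajectory
from diamoco.tracking import (
    FitFailure,
    ParabolaModel,
    ParabolicBand,
    RansacConfig,
    TrackingConfig,
    TrackingState,
    constrain,
    extract_edge_points,
    fit_parabola_ransac,
    parabolic_roi,
    rect_roi,
    track_sequence,
)


class TestParabolaModel:
    def test_vertex(self):
        m = ParabolaModel(a=1.0, b=2.0, c=3.0)
        assert m.vertex == pytest.approx((-1.0, 2.0))

    def test_translated_preserves_shape(self):
        m = ParabolaModel(a=0.01, b=-2.0, c=400.0)
        t = m.translated(7.5)
        assert t.a == m.a
        assert t.vertex[0] == pytest.approx(m.vertex[0] + 7.5)
        assert t.vertex[1] == pytest.approx(m.vertex[1])

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ParabolaModel(a=0.0, b=1.0, c=2.0)


class TestRois:
    def test_rect_roi_centered_sizes(self):
        r = rect_roi((320, 240), width=250, height=55)
        assert (r.u_min, r.u_max) == (195, 445)
        assert (r.v_min, r.v_max) == (212, 268)

    def test_rect_roi_clipped_at_corner(self):
        r = rect_roi((2, 3), width=250, height=55, image_shape=(480, 640))
        assert r.u_min == 0 and r.v_min == 0
        assert not r.is_empty()

    def test_parabolic_band_membership(self):
        m = ParabolaModel(a=0.01, b=0.0, c=100.0)
        band = parabolic_roi(m, band_height=21.0, u_range=(-50, 50))
        assert band.contains(0.0, 100.0)  # on the curve
        assert band.contains(0.0, 110.0) and band.contains(0.0, 90.0)  # symmetric
        assert not band.contains(0.0, 111.0)  # 11 px above a 21-px band
        assert not band.contains(60.0, 136.0)  # outside the u-range


class TestEdgeExtraction:
    def test_blank_image_gives_no_points(self):
        img = np.zeros((120, 160))
        pts = extract_edge_points(img, rect_roi((80, 60), 100, 40, img.shape))
        assert pts.shape == (0, 2)

    def test_step_edge_recovered_near_curve(self):
        # intensity step across v = 0.01 u^2 + 40
        u = np.arange(200)
        v = np.arange(120)
        curve = 0.01 * u**2 + 40.0
        img = (v[:, None] > curve[None, :]).astype(float)
        pts = extract_edge_points(img, rect_roi((60, 70), 100, 60, img.shape), gauss_sigma=1.0)
        assert len(pts) > 20
        resid = np.abs(pts[:, 1] - (0.01 * pts[:, 0] ** 2 + 40.0))
        assert resid.max() <= 1.0

    def test_roi_off_the_edge_is_empty(self):
        u = np.arange(200)
        img = (np.arange(120)[:, None] > (0.01 * u**2 + 40.0)[None, :]).astype(float)
        pts = extract_edge_points(img, rect_roi((60, 10), 100, 12, img.shape))
        assert len(pts) == 0

    def test_disjoint_roi_raises(self):
        img = np.zeros((50, 50))
        with pytest.raises(ValueError):
            extract_edge_points(img, rect_roi((500, 500), 20, 20))


def _ransac_fixture(rng_seed=42):
    """60 exact points on v = 0.01u^2 - 2u + 400 plus 40 far outliers."""
    rng = np.random.default_rng(rng_seed)
    u_in = np.linspace(50.0, 150.0, 60)
    v_in = 0.01 * u_in**2 - 2.0 * u_in + 400.0
    inliers = np.stack([u_in, v_in], axis=1)
    outliers = []
    while len(outliers) < 40:
        u = rng.uniform(40.0, 160.0)
        v = rng.uniform(v_in.min() - 40.0, v_in.max() + 40.0)
        if abs(v - (0.01 * u**2 - 2.0 * u + 400.0)) > 2.0:  # clearly not inliers
            outliers.append((u, v))
    return np.concatenate([inliers, np.asarray(outliers)]), inliers


class TestRansac:
    def test_three_points_exact(self):
        m, n = fit_parabola_ransac(np.array([[0.0, 3.0], [1.0, 6.0], [2.0, 11.0]]))
        assert (m.a, m.b, m.c) == pytest.approx((1.0, 2.0, 3.0))
        assert n == 3

    def test_seeded_fixture_recovers_exact_inlier_set(self):
        pts, inliers = _ransac_fixture()
        model, count = fit_parabola_ransac(pts, RansacConfig(), rng_seed=7)
        assert count == 60
        resid = np.abs(model(pts[:, 0]) - pts[:, 1])
        assert np.array_equal(np.flatnonzero(resid <= 1.0), np.arange(60))
        # refit equals the least-squares oracle on the generating set
        oracle = np.polyfit(inliers[:, 0], inliers[:, 1], 2)
        assert (model.a, model.b, model.c) == pytest.approx(tuple(oracle), abs=1e-6)

    def test_determinism(self):
        pts, _ = _ransac_fixture()
        m1, c1 = fit_parabola_ransac(pts, rng_seed=123)
        m2, c2 = fit_parabola_ransac(pts, rng_seed=123)
        assert (m1.a, m1.b, m1.c) == (m2.a, m2.b, m2.c) and c1 == c2

    def test_too_few_points(self):
        with pytest.raises(FitFailure):
            fit_parabola_ransac(np.array([[0.0, 1.0], [1.0, 2.0]]))

    def test_collinear_in_u_fails(self):
        pts = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0], [5.0, 4.0]])
        with pytest.raises(FitFailure):
            fit_parabola_ransac(pts)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            RansacConfig(n_models=0)
        with pytest.raises(ValueError):
            RansacConfig(inlier_tol=0.0)


class TestConstraints:
    def _state(self, a=0.01, **kw):
        st = TrackingState(prev_model=ParabolaModel(a=a, b=-2.0, c=400.0))
        st.n_du = 5
        st.mean_abs_du = 2.0
        for k, v in kw.items():
            setattr(st, k, v)
        return st

    def test_deformation_boundary(self):
        cfg = TrackingConfig()
        ok = constrain(ParabolaModel(a=0.0104, b=-2.08, c=400.0), self._state(), cfg)
        assert ok.accepted
        bad = constrain(ParabolaModel(a=0.0110, b=-2.2, c=400.0), self._state(), cfg)
        assert not bad.accepted and bad.reason == "deformation"

    def test_motion_limit(self):
        cfg = TrackingConfig()
        cand = ParabolaModel(a=0.01, b=-2.2, c=400.0)  # vertex u = 110 vs prev 100
        res = constrain(cand, self._state(), cfg)
        assert not res.accepted and res.reason == "motion"

    def test_direction_constraint_and_free_window(self):
        cfg = TrackingConfig()
        prev = ParabolaModel(a=0.01, b=-2.0, c=400.0)
        cand = prev.translated(3.0)  # moves right
        st = self._state(expected_direction="left")
        res = constrain(cand, st, cfg)
        assert not res.accepted and res.reason == "direction"
        assert constrain(cand, st, cfg, in_free_window=True).accepted


def _tiny_stack():
    """Small stack with one dome for fast end-to-end tracking tests."""
    det = DetectorSpec(nu=160, nv=120, spacing_u=2.464, spacing_v=2.464)
    # 4 deg/view keeps the per-frame vertex motion small enough for the
    # small-motion constraints, which are calibrated for ~1 deg/view scans
    geom = make_circular_trajectory(24, increment=4.0, scan_time=4.0, detector=det)
    spec = PhantomSpec(
        primitives=[
            Ellipsoid((0, 0, 0), (150, 100, 180), 0.02, name="body"),
            Ellipsoid(
                (30, 0, -50), (24, 26, 22), 0.03, moving=True,
                clip_plane=((0.0, 0.0, 1.0), -50.0), name="dome_r",
            ),
        ],
        amplitude_mm=10.0,
        period_s=4.0,
        tracked_apex=(30.0, 0.0, -28.0),
    )
    stack = forward_project(spec, geom)
    from diamoco.geometry import project_point
    from diamoco.simulator import diaphragm_top_truth

    truth = np.asarray(
        [
            project_point(geom.matrices[i], diaphragm_top_truth(spec, t))
            for i, t in enumerate(geom.timestamps)
        ]
    )
    return stack, geom, truth


@pytest.fixture(scope="module")
def tiny():
    return _tiny_stack()


class TestTrackSequence:

    def test_tracks_near_truth_and_is_deterministic(self, tiny):
        stack, geom, truth = tiny
        res1 = track_sequence(stack, truth[0], rng_seed=5, angles_deg=geom.angles)
        res2 = track_sequence(stack, truth[0], rng_seed=5, angles_deg=geom.angles)
        v1 = np.array([r.vertex for r in res1])
        v2 = np.array([r.vertex for r in res2])
        assert np.array_equal(v1, v2)
        assert len(res1) == geom.n_views
        err = np.linalg.norm(v1 - truth, axis=1)
        # quarter-resolution detector (2.46 mm/px): ~1 px mean is expected
        assert err.mean() < 1.5
        assert err.max() < 2.5

    def test_deformation_chain_bound(self, tiny):
        """Accepted tracks keep |a_t / a_{t-1}| within the 5% deformation cap."""
        stack, geom, truth = tiny
        res = track_sequence(stack, truth[0], rng_seed=5, angles_deg=geom.angles)
        a = np.array([r.model.a for r in res])
        ratios = a[1:] / a[:-1]
        # frames 0-1 are unconstrained by design; the rest obey the cap
        assert np.all(ratios[2:] >= 0.95 - 1e-9)
        assert np.all(ratios[2:] <= 1.05 + 1e-9)

    def test_seed_outside_frame_rejected(self, tiny):
        stack, geom, _ = tiny
        with pytest.raises(ValueError):
            track_sequence(stack, (1000.0, 10.0), rng_seed=0)
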