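"""Model-based diaphragm-contour tracking in rotational projection images.

The hemidiaphragm appears in a projection as a bright dome whose upper contour
is well approximated by a detector-space parabola v = a u^2 + b u + c (v
points down, so a tracked dome has a > 0 and its apex is the vertex, the
minimum in v). Each frame is processed as: region of interest around the
previous vertex -> gaussian smoothing + Canny edge detection -> RANSAC
parabola fit from 3-point samples -> plausibility constraints (limited
horizontal motion, <= 5% deformation of the curvature parameter, consistent
horizontal motion direction away from the turning point). The accepted
vertex seeds the next frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from scipy.ndimage import gaussian_gradient_magnitude

__all__ = [
    "ParabolaModel",
    "RansacConfig",
    "TrackingConfig",
    "TrackingState",
    "Rect",
    "ParabolicBand",
    "FitFailure",
    "rect_roi",
    "parabolic_roi",
    "extract_edge_points",
    "fit_parabola_ransac",
    "constrain",
    "track_sequence",
]

REFERENCE_DETECTOR = (640, 480)  # ROI sizes below are stated for this size


class FitFailure(Exception):
    """Raised when no parabola can be estimated from the edge points."""


@dataclass(frozen=True)
class ParabolaModel:
    """Detector-space quadratic v = a u^2 + b u + c (pixel units)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a == 0 or not np.isfinite(self.a + self.b + self.c):
            raise ValueError("degenerate parabola (a must be nonzero and finite)")

    @property
    def vertex(self) -> tuple[float, float]:
        u = -self.b / (2.0 * self.a)
        return (u, self.c - self.b**2 / (4.0 * self.a))

    def translated(self, du: float) -> "ParabolaModel":
        """The same parabola shifted horizontally by ``du`` pixels."""
        return ParabolaModel(
            a=self.a,
            b=self.b - 2.0 * self.a * du,
            c=self.c + self.a * du**2 - self.b * du,
        )

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        return self.a * u**2 + self.b * u + self.c


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC settings: number of sampled 3-point models, the inlier distance
    (vertical, px) and whether the winning model is least-squares refit on its
    inliers."""

    n_models: int = 20000
    inlier_tol: float = 1.0
    min_points: int = 3
    refit: bool = True

    def __post_init__(self) -> None:
        if self.n_models < 1 or self.inlier_tol <= 0 or self.min_points < 3:
            raise ValueError("invalid RANSAC configuration")


@dataclass(frozen=True)
class TrackingConfig:
    """Full tracker configuration.

    ROI sizes are given for a 640x480 detector and scale linearly with the
    actual detector resolution. ``motion_factor``/``motion_floor_px``
    operationalize the limited-horizontal-motion constraint: a candidate is
    rejected when its vertex moved more than max(factor * running mean |du*|,
    floor). ``free_window_deg`` is the half-width of the free-motion window
    around the turning point (the view looking along the anterior-posterior
    axis)."""

    roi_width: int = 250
    roi_height: int = 55
    band_height: float = 21.0
    # one-sided silhouette edges are localized with a bias toward the bright
    # side that grows with the smoothing scale; sigma = 1 px keeps the contour
    # sub-pixel accurate while still suppressing pixel noise
    gauss_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.3
    ransac: RansacConfig = field(default_factory=RansacConfig)
    deformation_limit: float = 0.05
    motion_factor: float = 2.0
    motion_floor_px: float = 3.0
    free_window_deg: float = 15.0
    initial_direction: str = "auto"  # "left", "right", "free" or "auto"
    direction_warmup: int = 5


@dataclass
class TrackingState:
    """Chained state between frames."""

    prev_model: ParabolaModel
    mean_abs_du: float = 0.0
    n_du: int = 0
    expected_direction: str = "free"
    frame_index: int = 0
    recent_du: list = field(default_factory=list)  # signed, accepted frames only

    def update_motion(self, du: float, accepted: bool = True) -> None:
        self.n_du += 1
        self.mean_abs_du += (abs(du) - self.mean_abs_du) / self.n_du
        if accepted:
            self.recent_du.append(du)
            del self.recent_du[:-5]

    def predicted_du(self) -> float:
        """Recent median per-frame vertex drift (constant-velocity prediction)."""
        return float(np.median(self.recent_du)) if self.recent_du else 0.0


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [u_min, u_max) x [v_min, v_max)."""

    u_min: int
    u_max: int
    v_min: int
    v_max: int

    def is_empty(self) -> bool:
        return self.u_max <= self.u_min or self.v_max <= self.v_min


@dataclass(frozen=True)
class ParabolicBand:
    """Band of +-height/2 px (vertically) around a parabola, limited to the
    u-range of the enclosing rectangular ROI."""

    model: ParabolaModel
    height: float
    u_min: float
    u_max: float

    def contains(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return (
            (np.abs(v - self.model(u)) <= self.height / 2.0)
            & (u >= self.u_min)
            & (u < self.u_max)
        )


def rect_roi(seed, width: int = 250, height: int = 55, image_shape=None) -> Rect:
    """Rectangle centered symmetrically on the seed, rounded outward and
    clipped to the image."""
    u, v = float(seed[0]), float(seed[1])
    r = Rect(
        int(np.floor(u - width / 2.0)),
        int(np.ceil(u + width / 2.0)),
        int(np.floor(v - height / 2.0)),
        int(np.ceil(v + height / 2.0)),
    )
    if image_shape is not None:
        nv, nu = image_shape
        r = Rect(max(r.u_min, 0), min(r.u_max, nu), max(r.v_min, 0), min(r.v_max, nv))
        if r.is_empty():
            raise ValueError("ROI does not intersect the image")
    return r


def parabolic_roi(prev: ParabolaModel, band_height: float = 21.0, u_range=None) -> ParabolicBand:
    """Band around the previous frame's model; ``u_range`` defaults to the
    rectangular ROI's u-extent around the previous vertex."""
    if u_range is None:
        u_star = prev.vertex[0]
        u_range = (u_star - 125.0, u_star + 125.0)
    return ParabolicBand(model=prev, height=band_height, u_min=u_range[0], u_max=u_range[1])


def extract_edge_points(
    image: np.ndarray,
    roi,
    gauss_sigma: float = 2.0,
    canny_low: float = 0.1,
    canny_high: float = 0.3,
) -> np.ndarray:
    """Canny edge pixels inside the ROI, as an (n, 2) array of (u, v).

    ``roi`` is a Rect or a ParabolicBand (the band implies the rectangle that
    bounds it vertically). Hysteresis thresholds are fractions of the ROI's
    maximum gaussian-gradient magnitude. Returns an empty array when the ROI
    contains no edges.
    """
    nv, nu = image.shape
    if isinstance(roi, ParabolicBand):
        band = roi
        us = np.arange(max(int(np.floor(band.u_min)), 0), min(int(np.ceil(band.u_max)), nu))
        if us.size == 0:
            raise ValueError("ROI does not intersect the image")
        curve = band.model(us)
        rect = Rect(
            int(us[0]),
            int(us[-1]) + 1,
            max(int(np.floor(curve.min() - band.height / 2.0)), 0),
            min(int(np.ceil(curve.max() + band.height / 2.0)) + 1, nv),
        )
    else:
        band = None
        rect = Rect(max(roi.u_min, 0), min(roi.u_max, nu), max(roi.v_min, 0), min(roi.v_max, nv))
    if rect.is_empty():
        raise ValueError("ROI does not intersect the image")
    crop = np.asarray(image[rect.v_min : rect.v_max, rect.u_min : rect.u_max], dtype=float)
    gmax = float(gaussian_gradient_magnitude(crop, gauss_sigma).max())
    if gmax == 0.0:
        return np.empty((0, 2))
    edges = canny(
        crop,
        sigma=gauss_sigma,
        low_threshold=canny_low * gmax,
        high_threshold=canny_high * gmax,
    )
    vs, us = np.nonzero(edges)
    pts = np.stack([us + rect.u_min, vs + rect.v_min], axis=1).astype(float)
    if band is not None:
        pts = pts[band.contains(pts[:, 0], pts[:, 1])]
    return pts


def _ls_refit(points: np.ndarray) -> ParabolaModel:
    a, b, c = np.polyfit(points[:, 0], points[:, 1], 2)
    return ParabolaModel(a=float(a), b=float(b), c=float(c))


def fit_parabola_ransac(
    points: np.ndarray,
    cfg: RansacConfig | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[ParabolaModel, int]:
    """Best-of-N exact 3-point parabola fits scored by inlier count.

    An inlier lies within ``cfg.inlier_tol`` px vertical distance of the model.
    Ties are broken by smaller mean inlier residual, then by lower sample
    index. When ``cfg.refit`` the winner is least-squares refit on its inlier
    set. Deterministic given the seed.

    Raises FitFailure when fewer than 3 points are given or all samples are
    degenerate (shared u coordinates).
    """
    cfg = cfg or RansacConfig()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < cfg.min_points:
        raise FitFailure(f"need at least {cfg.min_points} edge points")
    m = pts.shape[0]
    u, v = pts[:, 0], pts[:, 1]
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    N = cfg.n_models
    idx = rng.integers(0, m, size=(N, 3))
    uu = u[idx]  # (N, 3)
    vv = v[idx]
    # exact 3-point fit via Cramer's rule on the Vandermonde system
    u1, u2, u3 = uu[:, 0], uu[:, 1], uu[:, 2]
    det = (u1 - u2) * (u1 - u3) * (u2 - u3)
    valid = np.abs(det) > 1e-12
    if not np.any(valid):
        raise FitFailure("all sampled triples are collinear in u")
    with np.errstate(divide="ignore", invalid="ignore"):
        v1, v2, v3 = vv[:, 0], vv[:, 1], vv[:, 2]
        a = (v1 * (u2 - u3) - v2 * (u1 - u3) + v3 * (u1 - u2)) / det
        b = (
            -(v1 * (u2**2 - u3**2) - v2 * (u1**2 - u3**2) + v3 * (u1**2 - u2**2))
            / det
        )
        c = (
            v1 * u2 * u3 * (u2 - u3)
            - v2 * u1 * u3 * (u1 - u3)
            + v3 * u1 * u2 * (u1 - u2)
        ) / det
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, np.inf)  # invalid models attract no inliers
    counts = np.zeros(N, dtype=np.int64)
    chunk = max(1, int(5e6) // max(m, 1))
    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        pred = (
            a[lo:hi, None] * u[None, :] ** 2
            + b[lo:hi, None] * u[None, :]
            + c[lo:hi, None]
        )
        counts[lo:hi] = np.sum(np.abs(pred - v[None, :]) <= cfg.inlier_tol, axis=1)
    counts[~valid] = -1
    best_count = counts.max()
    if best_count < cfg.min_points:
        raise FitFailure("no model attracted enough inliers")
    cand = np.flatnonzero(counts == best_count)
    if cand.size > 1:
        # tie-break: smallest mean inlier residual, then lowest model index
        means = np.empty(cand.size)
        for j, ci in enumerate(cand):
            res = np.abs(a[ci] * u**2 + b[ci] * u + c[ci] - v)
            means[j] = res[res <= cfg.inlier_tol].mean()
        cand = cand[np.lexsort((cand, means))]
    best = int(cand[0])
    model = ParabolaModel(a=float(a[best]), b=float(b[best]), c=float(c[best]))
    inl = np.abs(model(u) - v) <= cfg.inlier_tol
    if cfg.refit and inl.sum() >= 3 and np.unique(u[inl]).size >= 3:
        refit = _ls_refit(pts[inl])
        # the refit must not lose the consensus that elected the model
        if np.sum(np.abs(refit(u) - v) <= cfg.inlier_tol) >= best_count:
            model = refit
    return model, int(best_count)


@dataclass(frozen=True)
class ConstraintResult:
    model: ParabolaModel
    accepted: bool
    reason: str = ""


def constrain(
    candidate: ParabolaModel,
    state: TrackingState,
    cfg: TrackingConfig,
    in_free_window: bool = False,
) -> ConstraintResult:
    """Apply the three tracking plausibility constraints to a candidate model.

    (i) the vertex's horizontal motion may not exceed
    max(motion_factor * running mean |du*|, motion_floor_px);
    (ii) the curvature parameter a may not change by more than
    ``deformation_limit`` relative to the previous model;
    (iii) outside the free-motion window around the turning point, the vertex
    must move in the expected horizontal direction.
    """
    prev = state.prev_model
    if abs(candidate.a - prev.a) / abs(prev.a) > cfg.deformation_limit:
        return ConstraintResult(candidate, False, "deformation")
    du = candidate.vertex[0] - prev.vertex[0]
    if state.n_du > 0:
        limit = max(cfg.motion_factor * state.mean_abs_du, cfg.motion_floor_px)
        if abs(du) > limit:
            return ConstraintResult(candidate, False, "motion")
    if not in_free_window and state.expected_direction in ("left", "right"):
        if state.expected_direction == "left" and du > 0:
            return ConstraintResult(candidate, False, "direction")
        if state.expected_direction == "right" and du < 0:
            return ConstraintResult(candidate, False, "direction")
    return ConstraintResult(candidate, True)


def _fallback_model(
    prev: ParabolaModel, points: np.ndarray, tol: float, du_pred: float = 0.0
) -> ParabolaModel:
    """Replacement for a rejected candidate.

    Dead-reckon the previous model along the recent vertex drift (the
    small-motion assumption as a constant-velocity prediction), then refit b, c
    by trimmed least squares around that prediction with the curvature a held
    fixed. If the refit strays from the prediction — as happens when an
    interfering contour crosses the band — the prediction itself is kept.
    """
    predicted = prev.translated(du_pred)
    if points.shape[0] == 0:
        return predicted
    u, v = points[:, 0], points[:, 1]
    model = predicted
    for band in (2.0 * tol, 1.5 * tol, 1.5 * tol):
        near = np.abs(model(u) - v) <= band
        if near.sum() < 2:
            return model
        rhs = v[near] - prev.a * u[near] ** 2
        A = np.stack([u[near], np.ones(int(near.sum()))], axis=1)
        (b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
        model = ParabolaModel(a=prev.a, b=float(b), c=float(c))
    if abs(model.vertex[0] - predicted.vertex[0]) > 3.0:
        return predicted
    return model


def _free_window(angles_deg: np.ndarray, half_width_deg: float) -> np.ndarray:
    """True for views whose optical axis is within the window around the
    anterior-posterior direction (world +-y)."""
    # optical axis at gantry angle theta is -(cos t, sin t, 0); AP at t = 90/270
    d = np.abs((angles_deg % 180.0) - 90.0)
    return d <= half_width_deg


@dataclass
class TrackResult:
    """Per-frame tracking output."""

    frame: int
    model: ParabolaModel
    vertex: tuple[float, float]
    n_inliers: int
    constrained: bool = False
    fit_failed: bool = False


def track_sequence(
    stack: np.ndarray,
    seed,
    cfg: TrackingConfig | None = None,
    rng_seed: int = 0,
    angles_deg: np.ndarray | None = None,
) -> list[TrackResult]:
    """Track the diaphragm contour through a projection stack.

    Frame 0 uses a rectangular ROI centered on the user seed; later frames use
    the parabolic band around the previous model (recentering the rectangular
    u-extent on the previous vertex). Constraint rejections fall back to the
    previous model with b, c refit on the current frame; fit failures carry
    the previous model over, flagged. Deterministic given ``rng_seed``.

    ``angles_deg`` (per-view gantry angles) enables the direction constraint
    and its free-motion window; without it the direction is unconstrained.
    """
    cfg = cfg or TrackingConfig()
    stack = np.asarray(stack)
    n, nv, nu = stack.shape
    if not (0 <= seed[0] < nu and 0 <= seed[1] < nv):
        raise ValueError("seed point outside frame 0")
    su = nu / REFERENCE_DETECTOR[0]
    sv = nv / REFERENCE_DETECTOR[1]
    width = max(int(round(cfg.roi_width * su)), 8)
    height = max(int(round(cfg.roi_height * sv)), 4)
    band_height = max(cfg.band_height * sv, 3.0)
    rng = np.random.default_rng(rng_seed)
    free = (
        _free_window(np.asarray(angles_deg, dtype=float), cfg.free_window_deg)
        if angles_deg is not None
        else np.zeros(n, dtype=bool)
    )
    results: list[TrackResult] = []
    state: TrackingState | None = None
    du_history: list[float] = []
    direction = cfg.initial_direction if cfg.initial_direction != "auto" else "free"
    flipped = False
    for i in range(n):
        frame_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        if state is None:
            roi = rect_roi(seed, width, height, image_shape=(nv, nu))
        else:
            u_star = state.prev_model.vertex[0]
            roi = parabolic_roi(
                state.prev_model, band_height, u_range=(u_star - width / 2.0, u_star + width / 2.0)
            )
        pts = extract_edge_points(stack[i], roi, cfg.gauss_sigma, cfg.canny_low, cfg.canny_high)
        try:
            model, n_inl = fit_parabola_ransac(pts, cfg.ransac, frame_rng)
            failed = False
        except FitFailure:
            model, n_inl, failed = (state.prev_model if state else None), 0, True
            if model is None:
                raise
        constrained_flag = False
        if state is not None and not failed and i >= 2:
            # flip the expected direction once the turning point has passed
            if angles_deg is not None and not flipped and i > 0 and free[i - 1] and not free[i]:
                if direction in ("left", "right"):
                    direction = "left" if direction == "right" else "right"
                flipped = True
            state.expected_direction = direction
            res = constrain(model, state, cfg, in_free_window=bool(free[i]))
            if not res.accepted:
                model = _fallback_model(
                    state.prev_model, pts, cfg.ransac.inlier_tol, state.predicted_du()
                )
                constrained_flag = True
        if state is None:
            state = TrackingState(prev_model=model, frame_index=i)
        else:
            du = model.vertex[0] - state.prev_model.vertex[0]
            state.update_motion(du, accepted=not (constrained_flag or failed))
            du_history.append(du)
            if (
                cfg.initial_direction == "auto"
                and direction == "free"
                and len(du_history) == cfg.direction_warmup
            ):
                s = float(np.sum(du_history))
                if s != 0:
                    direction = "left" if s < 0 else "right"
            state.prev_model = model
            state.frame_index = i
        results.append(
            TrackResult(
                frame=i,
                model=model,
                vertex=model.vertex,
                n_inliers=n_inl,
                constrained=constrained_flag,
                fit_failed=failed,
            )
        )
    return results


def track_to_dataframe(results: list[TrackResult]):
    """Tracking results as a pandas DataFrame (one row per frame)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": [r.frame for r in results],
            "a": [r.model.a for r in results],
            "b": [r.model.b for r in results],
            "c": [r.model.c for r in results],
            "u_vertex": [r.vertex[0] for r in results],
            "v_vertex": [r.vertex[1] for r in results],
            "n_inliers": [r.n_inliers for r in results],
            "constrained_flag": [r.constrained or r.fit_failed for r in results],
        }
    )
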