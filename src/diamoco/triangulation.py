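"""Motion-corrected stereo triangulation of the per-frame diaphragm vertex.

Standard two-view triangulation assumes a static scene; during breathing the
diaphragm top moves between the two acquisition times, so naive triangulation
is biased by a substantial fraction of the respiratory excursion. The remedy
implemented here: rectify the image pair onto a common plane (epipolar lines
horizontal), where a static point has equal vertical coordinates in both
views; any residual vertical disparity is therefore attributable to
superior-inferior motion and is removed by copying the reference view's
vertical coordinate into the partner view before triangulating. With the
rotation axis parallel to the SI axis the rectified vertical coordinate
depends on world z only, so for pure SI motion the corrected pair triangulates
exactly to the point's position at the reference view's acquisition time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import decompose_projection_matrix

__all__ = [
    "RectifiedPair",
    "rectify_pair",
    "motion_correct",
    "triangulate_linear_eigen",
    "triangulate_sequence",
]


@dataclass
class RectifiedPair:
    """Rectified camera pair: new projection matrices sharing intrinsics and
    rotation, plus 3x3 pixel transforms from original to rectified
    coordinates."""

    P_i: np.ndarray
    P_j: np.ndarray
    T_i: np.ndarray
    T_j: np.ndarray

    def transform(self, T: np.ndarray, uv) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        h = T @ np.array([uv[0], uv[1], 1.0])
        return h[:2] / h[2]


def rectify_pair(P_i: np.ndarray, P_j: np.ndarray) -> RectifiedPair:
    """Rectification of a camera pair onto a common image plane.

    Both new cameras keep their optical centers but share a rotation whose
    x-axis is the baseline direction (and shared intrinsics), which makes
    epipolar lines horizontal: a static 3D point projects to the same vertical
    coordinate in both rectified views.
    """
    K1, R1, c1 = decompose_projection_matrix(P_i)
    K2, R2, c2 = decompose_projection_matrix(P_j)
    baseline = c2 - c1
    nb = np.linalg.norm(baseline)
    if nb < 1e-9:
        raise ValueError("coincident camera centers: cannot rectify")
    r1 = baseline / nb
    # new y-axis orthogonal to the baseline and to the first camera's optical axis
    z_old = R1[2]
    r2 = np.cross(z_old, r1)
    n2 = np.linalg.norm(r2)
    if n2 < 1e-9:
        raise ValueError("baseline parallel to the optical axis: degenerate pair")
    r2 /= n2
    r3 = np.cross(r1, r2)
    R = np.stack([r1, r2, r3])
    K = (K1 + K2) / 2.0
    K[0, 1] = 0.0  # no skew in the rectified cameras
    Pn_i = K @ np.hstack([R, (-R @ c1)[:, None]])
    Pn_j = K @ np.hstack([R, (-R @ c2)[:, None]])
    T_i = (K @ R) @ np.linalg.inv(K1 @ R1)
    T_j = (K @ R) @ np.linalg.inv(K2 @ R2)
    return RectifiedPair(P_i=Pn_i, P_j=Pn_j, T_i=T_i, T_j=T_j)


def motion_correct(g_rect: np.ndarray, gp_rect: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove SI motion from a rectified correspondence.

    The first (reference) point is untouched; the partner keeps its horizontal
    coordinate and adopts the reference's vertical coordinate, so the returned
    pair has zero vertical disparity by construction.
    """
    g = np.asarray(g_rect, dtype=float)
    gp = np.asarray(gp_rect, dtype=float)
    return g.copy(), np.array([gp[0], g[1]])


def triangulate_linear_eigen(
    P_i: np.ndarray,
    P_j: np.ndarray,
    g,
    gp,
    iterative: bool = True,
    max_iter: int = 10,
    tol: float = 1e-10,
) -> np.ndarray:
    """Two-view homogeneous linear (Linear-Eigen) triangulation.

    Builds the 4x4 system from both projections and takes the smallest right
    singular vector. The iterative variant reweights each view's two equations
    by the inverse of the current depth estimate and repeats until the point
    moves less than ``tol`` (mm) or ``max_iter`` is reached, which approximates
    minimizing image-plane (rather than algebraic) error.
    """
    g = np.asarray(g, dtype=float)
    gp = np.asarray(gp, dtype=float)
    rows = []
    for P, (u, v) in ((P_i, g), (P_j, gp)):
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
    A = np.asarray(rows)
    norm = np.linalg.norm(A[:, :3], axis=1)
    if np.linalg.matrix_rank(A / np.maximum(norm, 1e-300)[:, None], tol=1e-9) < 3:
        raise ValueError("degenerate triangulation system (parallel rays)")

    def solve(Aw: np.ndarray) -> np.ndarray:
        _, _, Vt = np.linalg.svd(Aw)
        Xh = Vt[-1]
        if abs(Xh[3]) < 1e-14:
            raise ValueError("triangulated point at infinity")
        return Xh[:3] / Xh[3]

    X = solve(A)
    if not iterative:
        return X
    for _ in range(max_iter):
        w1 = P_i[2] @ np.append(X, 1.0)
        w2 = P_j[2] @ np.append(X, 1.0)
        if abs(w1) < 1e-12 or abs(w2) < 1e-12:
            break
        W = np.array([1.0 / w1, 1.0 / w1, 1.0 / w2, 1.0 / w2])
        X_new = solve(A * W[:, None])
        if np.linalg.norm(X_new - X) < tol:
            X = X_new
            break
        X = X_new
    return X


def triangulate_pair(
    P_i: np.ndarray,
    P_j: np.ndarray,
    g,
    gp,
    mode: str = "rectified_corrected",
    iterative: bool = True,
) -> np.ndarray:
    """Triangulate one correspondence in either pipeline mode.

    "rectified_corrected": rectify, zero the vertical disparity (reference =
    first view), triangulate with the rectified matrices. "standard": plain
    triangulation of the raw correspondence.
    """
    if mode == "standard":
        return triangulate_linear_eigen(P_i, P_j, g, gp, iterative=iterative)
    if mode != "rectified_corrected":
        raise ValueError(f"unknown mode {mode!r}")
    pair = rectify_pair(P_i, P_j)
    gr = pair.transform(pair.T_i, g)
    gpr = pair.transform(pair.T_j, gp)
    gr, gpr = motion_correct(gr, gpr)
    return triangulate_linear_eigen(pair.P_i, pair.P_j, gr, gpr, iterative=iterative)


def triangulate_sequence(
    vertices: np.ndarray,
    geom,
    offset_deg: float = 90.0,
    mode: str = "rectified_corrected",
    iterative: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate every frame's vertex against a partner frame.

    Frame i pairs with i+k (k views ~ ``offset_deg`` at the trajectory's
    angular increment) when available, falling back to i-k near the end of the
    sequence; frame i is always the reference of the motion correction, so the
    output point is attributed to frame i's acquisition time.

    Returns (points (n,3) mm, partner indices (n,)).
    """
    vertices = np.asarray(vertices, dtype=float)
    n = geom.n_views
    if vertices.shape != (n, 2):
        raise ValueError("vertices must be (n_views, 2)")
    increment = np.abs(np.diff(geom.angles)).mean()
    k = int(round(offset_deg / increment))
    if k < 1 or k >= n:
        raise ValueError("angular offset not representable with this trajectory")
    points = np.empty((n, 3))
    partners = np.empty(n, dtype=int)
    for i in range(n):
        j = i + k if i + k < n else i - k
        partners[i] = j
        points[i] = triangulate_pair(
            geom.matrices[i],
            geom.matrices[j],
            vertices[i],
            vertices[j],
            mode=mode,
            iterative=iterative,
        )
    return points, partners
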