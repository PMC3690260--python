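"""Projective cone-beam geometry for circular C-arm trajectories.

World frame: z is the superior-inferior axis (the rotation axis), right-handed,
isocenter at the origin. Detector row coordinate v grows toward inferior
(image convention: v increases with decreasing world z); column coordinate u is
perpendicular to z. Pixel coordinates are 0-based with pixel-center convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorSpec",
    "ProjectionGeometry",
    "make_circular_trajectory",
    "project_point",
    "decompose_projection_matrix",
    "pixel_ray",
]


@dataclass(frozen=True)
class DetectorSpec:
    """Flat-panel detector: size in pixels, pixel pitch in mm, principal point.

    The principal point (u0, v0) is where the source-isocenter line pierces the
    detector, in 0-based pixel coordinates.
    """

    nu: int = 640
    nv: int = 480
    spacing_u: float = 0.616
    spacing_v: float = 0.616
    principal_point: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.nv <= 0:
            raise ValueError("detector size must be positive")
        if self.spacing_u <= 0 or self.spacing_v <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.principal_point is None:
            object.__setattr__(
                self, "principal_point", ((self.nu - 1) / 2.0, (self.nv - 1) / 2.0)
            )
        u0, v0 = self.principal_point
        if not (0 <= u0 < self.nu and 0 <= v0 < self.nv):
            raise ValueError("principal point must lie inside the detector")

    def to_dict(self) -> dict:
        return {
            "nu": self.nu,
            "nv": self.nv,
            "spacing_u": self.spacing_u,
            "spacing_v": self.spacing_v,
            "u0": self.principal_point[0],
            "v0": self.principal_point[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorSpec":
        return cls(
            nu=int(d["nu"]),
            nv=int(d["nv"]),
            spacing_u=float(d["spacing_u"]),
            spacing_v=float(d["spacing_v"]),
            principal_point=(float(d["u0"]), float(d["v0"])),
        )


@dataclass
class ProjectionGeometry:
    """Per-view projection matrices, source positions, angles and timestamps.

    ``matrices[i]`` is the 3x4 homogeneous projection P_i mapping world mm to
    detector px; ``source_positions[i]`` spans its null space.
    """

    matrices: np.ndarray  # (n_views, 3, 4)
    source_positions: np.ndarray  # (n_views, 3)
    angles: np.ndarray  # degrees
    timestamps: np.ndarray  # seconds
    detector: DetectorSpec
    sod: float = field(default=np.nan)
    sdd: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = self.matrices.shape[0]
        if self.matrices.shape != (n, 3, 4):
            raise ValueError("matrices must have shape (n_views, 3, 4)")
        for name in ("source_positions", "angles", "timestamps"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match n_views")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        hom = np.concatenate(
            [self.source_positions, np.ones((n, 1))], axis=1
        )  # (n, 4)
        resid = np.einsum("nij,nj->ni", self.matrices, hom)
        if not np.allclose(resid, 0.0, atol=1e-9):
            raise ValueError("source positions must span the null space of P")

    @property
    def n_views(self) -> int:
        return self.matrices.shape[0]

    def to_json(self, path) -> None:
        d = {
            "n_views": self.n_views,
            "matrices": self.matrices.reshape(self.n_views, 12).tolist(),
            "sources": self.source_positions.tolist(),
            "angles_deg": self.angles.tolist(),
            "timestamps_s": self.timestamps.tolist(),
            "detector": self.detector.to_dict(),
            "sod": None if np.isnan(self.sod) else self.sod,
            "sdd": None if np.isnan(self.sdd) else self.sdd,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "ProjectionGeometry":
        with open(path) as fh:
            d = json.load(fh)
        n = int(d["n_views"])
        return cls(
            matrices=np.asarray(d["matrices"], dtype=float).reshape(n, 3, 4),
            source_positions=np.asarray(d["sources"], dtype=float),
            angles=np.asarray(d["angles_deg"], dtype=float),
            timestamps=np.asarray(d["timestamps_s"], dtype=float),
            detector=DetectorSpec.from_dict(d["detector"]),
            sod=d.get("sod") or np.nan,
            sdd=d.get("sdd") or np.nan,
        )


def _camera_axes(angle_rad: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed camera frame (e_u, e_v, optical axis) at a gantry angle."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    axis = np.array([-c, -s, 0.0])  # source -> isocenter
    e_u = np.array([-s, c, 0.0])  # columns perpendicular to z; e_u x e_v = axis
    e_v = np.array([0.0, 0.0, -1.0])  # rows grow toward inferior
    return e_u, e_v, axis


def make_circular_trajectory(
    n_views: int,
    start_angle: float = 0.0,
    increment: float = 1.0,
    sod: float = 800.0,
    sdd: float = 1200.0,
    scan_time: float = 4.0,
    detector: DetectorSpec | None = None,
) -> ProjectionGeometry:
    """Build a circular short-scan trajectory around the z (SI) axis.

    The source at gantry angle theta sits at (sod*cos(theta), sod*sin(theta), 0);
    the detector plane is perpendicular to the source-isocenter line at distance
    ``sdd`` from the source. Timestamps are uniform on [0, scan_time).

    Parameters
    ----------
    n_views : number of projections (>= 2).
    start_angle, increment : gantry start angle and per-view increment in degrees.
    sod, sdd : source-isocenter and source-detector distances in mm.
    scan_time : total acquisition time in seconds.
    detector : detector spec; defaults to 640x480 at 0.616 mm/px.
    """
    if n_views < 2:
        raise ValueError("n_views must be >= 2")
    if not (0 < sod < sdd):
        raise ValueError("require 0 < sod < sdd")
    if scan_time <= 0:
        raise ValueError("scan_time must be positive")
    det = detector if detector is not None else DetectorSpec()
    u0, v0 = det.principal_point
    fu = sdd / det.spacing_u  # focal length in pixel units
    fv = sdd / det.spacing_v
    K = np.array([[fu, 0.0, u0], [0.0, fv, v0], [0.0, 0.0, 1.0]])

    angles = start_angle + increment * np.arange(n_views)
    matrices = np.empty((n_views, 3, 4))
    sources = np.empty((n_views, 3))
    for i, ang in enumerate(np.deg2rad(angles)):
        e_u, e_v, axis = _camera_axes(ang)
        c = sod * np.array([np.cos(ang), np.sin(ang), 0.0])
        R = np.stack([e_u, e_v, axis])  # world -> camera rotation
        P = K @ np.hstack([R, (-R @ c)[:, None]])
        matrices[i] = P
        sources[i] = c
    timestamps = scan_time * np.arange(n_views) / n_views
    return ProjectionGeometry(
        matrices=matrices,
        source_positions=sources,
        angles=angles,
        timestamps=timestamps,
        detector=det,
        sod=sod,
        sdd=sdd,
    )


def project_point(P: np.ndarray, X) -> np.ndarray:
    """Project world point(s) X (mm) with a 3x4 matrix; returns (u, v) in px.

    Accepts a single 3-vector or an (n, 3) array. Raises on points whose
    homogeneous depth is (numerically) zero, i.e. points in the source plane.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xh = np.concatenate(
        [np.atleast_2d(X), np.ones((np.atleast_2d(X).shape[0], 1))], axis=1
    )
    q = Xh @ P.T  # (n, 3)
    w = q[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("point projects to infinity (lies in the source plane)")
    uv = q[:, :2] / w[:, None]
    return uv[0] if single else uv


def pixel_ray(P: np.ndarray, source: np.ndarray, u: float, v: float) -> np.ndarray:
    """Unit direction of the ray from ``source`` through detector pixel (u, v)."""
    M = P[:, :3]
    d = np.linalg.solve(M, np.array([u, v, 1.0]))
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate pixel ray")
    d = d / n
    # orient away from the source toward the scene (positive depth)
    if (P @ np.append(source + d, 1.0))[2] < 0:
        d = -d
    return d


def decompose_projection_matrix(
    P: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split P = K [R | -R c] into intrinsics K, rotation R and center c.

    Uses the standard RQ decomposition of the left 3x3 block, with signs fixed
    so that K has a positive diagonal and det(R) = +1.
    """
    M = P[:, :3]
    # RQ via QR of the exchanged/transposed matrix
    E = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    Q_, R_ = np.linalg.qr((E @ M).T)
    K = E @ R_.T @ E
    R = E @ Q_.T
    # make K's diagonal positive
    S = np.diag(np.sign(np.diag(K)))
    K = K @ S
    R = S @ R
    if np.linalg.det(R) < 0:
        # P and -P are the same camera projectively; flip to a proper rotation
        R = -R
    c = -np.linalg.solve(M, P[:, 3])
    K = K / K[2, 2]
    return K, R, c
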