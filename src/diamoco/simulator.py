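"""Synthetic dynamic-thorax phantom with analytic forward projection.

The scene is a set of (optionally clipped) ellipsoids: a body, two lung
cavities, a heart with high-contrast lesions, and two diaphragm domes modelled
as upper-half ellipsoid caps. Breathing displaces the moving primitives (heart,
lesions, domes) rigidly along the superior-inferior axis; everything else is
static. Projections are exact line integrals (closed-form ray-ellipsoid
intersection), so tracking and triangulation can be validated against analytic
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .geometry import ProjectionGeometry
from .reconstruction import Volume

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "default_phantom",
    "breathing_displacement",
    "scene_at_time",
    "forward_project",
    "diaphragm_top_truth",
    "render_volume",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid primitive.

    ``attenuation`` is the linear attenuation in 1/mm added inside the
    primitive; negative values are allowed only for explicit cavity carving
    (``is_cavity=True``), e.g. low-density lungs inside the body. ``clip_plane``
    keeps the half-space n.x >= d, used for dome-shaped diaphragm caps.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    attenuation: float
    moving: bool = False
    is_cavity: bool = False
    clip_plane: tuple[tuple[float, float, float], float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.attenuation < 0 and not self.is_cavity:
            raise ValueError("negative attenuation requires is_cavity=True")

    def shifted(self, dz: float) -> "Ellipsoid":
        cx, cy, cz = self.center
        clip = self.clip_plane
        if clip is not None:
            (nx, ny, nz), d = clip
            clip = ((nx, ny, nz), d + nz * dz)
        return replace(self, center=(cx, cy, cz + dz), clip_plane=clip)


@dataclass
class PhantomSpec:
    """Primitive list plus the breathing law.

    ``amplitude_mm`` is the peak-to-peak superior-inferior excursion of the
    moving primitives over one cycle of length ``period_s``; the default curve
    is sin^2(pi t / period), i.e. one smooth inhale-exhale per period starting
    from end-exhale. ``tracked_apex`` is the time-zero position of the apex of
    the dome the tracker follows.
    """

    primitives: list[Ellipsoid]
    amplitude_mm: float = 23.0
    period_s: float = 4.0
    curve: str = "sin2"
    tracked_apex: tuple[float, float, float] = (50.0, 0.0, -28.0)

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period_s <= 0:
            raise ValueError("period must be positive")

    def to_yaml(self, path) -> None:
        d = {
            "amplitude_mm": self.amplitude_mm,
            "period_s": self.period_s,
            "curve": self.curve,
            "tracked_apex": list(self.tracked_apex),
            "primitives": [
                {
                    "center": list(p.center),
                    "semi_axes": list(p.semi_axes),
                    "attenuation": p.attenuation,
                    "moving": p.moving,
                    "is_cavity": p.is_cavity,
                    "clip_plane": None
                    if p.clip_plane is None
                    else [list(p.clip_plane[0]), p.clip_plane[1]],
                    "name": p.name,
                }
                for p in self.primitives
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        prims = [
            Ellipsoid(
                center=tuple(p["center"]),
                semi_axes=tuple(p["semi_axes"]),
                attenuation=float(p["attenuation"]),
                moving=bool(p.get("moving", False)),
                is_cavity=bool(p.get("is_cavity", False)),
                clip_plane=None
                if p.get("clip_plane") is None
                else (tuple(p["clip_plane"][0]), float(p["clip_plane"][1])),
                name=p.get("name", ""),
            )
            for p in d["primitives"]
        ]
        return cls(
            primitives=prims,
            amplitude_mm=float(d["amplitude_mm"]),
            period_s=float(d["period_s"]),
            curve=d.get("curve", "sin2"),
            tracked_apex=tuple(d.get("tracked_apex", (50.0, 0.0, -28.0))),
        )


def default_phantom(amplitude_mm: float = 23.0, period_s: float = 4.0) -> PhantomSpec:
    """Isocentric thorax layout (mm) with water-like attenuations (1/mm).

    Only relative contrast matters for the pipeline; the numbers are
    configuration, not constants. Lungs are carved as cavities (net ~0.0002/mm
    inside), and each diaphragm dome is an upper-half ellipsoid cap whose apex
    bulges into the bottom of a lung.
    """
    mu_body, mu_lung, mu_heart, mu_lesion, mu_dome = 0.02, 0.0002, 0.025, 0.04, 0.05
    # the heart lies fully inside the right lung cavity so its (moving)
    # boundary carries the soft-tissue/lung contrast, as in a real thorax;
    # each diaphragm dome is a near-spherical cap bulging into a lung base
    # (a strongly oblate cap would put its silhouette top pixels away from
    # the true apex projection under oblique perspective)
    prims = [
        Ellipsoid((0, 0, 0), (150, 100, 180), mu_body, name="body"),
        Ellipsoid((45, 0, 10), (42, 60, 92), mu_lung - mu_body, is_cavity=True, name="lung_r"),
        Ellipsoid((-45, 0, 10), (42, 60, 92), mu_lung - mu_body, is_cavity=True, name="lung_l"),
        Ellipsoid((45, 15, 40), (32, 34, 46), mu_heart - mu_lung, moving=True, name="heart"),
        Ellipsoid((53, 15, 30), (5, 5, 5), mu_lesion - mu_heart, moving=True, name="lesion_1"),
        Ellipsoid((35, 8, 60), (5, 5, 5), mu_lesion - mu_heart, moving=True, name="lesion_2"),
        Ellipsoid(
            (50, 0, -50), (24, 26, 22), mu_dome - mu_lung, moving=True,
            clip_plane=((0.0, 0.0, 1.0), -50.0), name="dome_r",
        ),
        Ellipsoid(
            (-50, 0, -50), (24, 26, 22), mu_dome - mu_lung, moving=True,
            clip_plane=((0.0, 0.0, 1.0), -50.0), name="dome_l",
        ),
    ]
    return PhantomSpec(
        primitives=prims,
        amplitude_mm=amplitude_mm,
        period_s=period_s,
        tracked_apex=(50.0, 0.0, -28.0),
    )


def breathing_displacement(t, spec: PhantomSpec):
    """Superior-inferior displacement (mm, >= 0) of the moving anatomy at time t.

    Periodic with ``spec.period_s`` and range exactly [0, amplitude]; the
    default shape is amplitude * sin^2(pi t / period).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if spec.curve != "sin2":
        raise ValueError(f"unknown breathing curve {spec.curve!r}")
    out = spec.amplitude_mm * np.sin(np.pi * t / spec.period_s) ** 2
    return float(out) if out.ndim == 0 else out


def scene_at_time(spec: PhantomSpec, t: float) -> list[Ellipsoid]:
    """Primitive list at time t: moving primitives shift by -displacement in z
    (anatomy moves inferior during inhale); static primitives are unchanged."""
    dz = -breathing_displacement(t, spec)
    return [p.shifted(dz) if p.moving else p for p in spec.primitives]


def diaphragm_top_truth(spec: PhantomSpec, t):
    """True 3D position (mm) of the tracked dome's apex at time t."""
    t = np.asarray(t, dtype=float)
    disp = np.asarray(breathing_displacement(t, spec))
    apex = np.asarray(spec.tracked_apex, dtype=float)
    out = np.broadcast_to(apex, disp.shape + (3,)).copy()
    out[..., 2] -= disp
    return out


def _ray_chords(prim: Ellipsoid, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Chord length (mm) of each unit-direction ray through the primitive.

    ``origins`` broadcastable to (n, 3); ``dirs`` (n, 3) unit vectors.
    """
    c = np.asarray(prim.center)
    a = np.asarray(prim.semi_axes)
    o = (origins - c) / a
    d = dirs / a
    # quadratic |o + t d|^2 = 1
    A = np.einsum("...i,...i->...", d, d)
    B = np.einsum("...i,...i->...", o, d)
    C = np.einsum("...i,...i->...", o, o) - 1.0
    disc = B * B - A * C
    hit = disc > 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t0 = np.where(hit, (-B - sq) / A, 0.0)
    t1 = np.where(hit, (-B + sq) / A, 0.0)
    if prim.clip_plane is not None:
        n, dplane = np.asarray(prim.clip_plane[0]), prim.clip_plane[1]
        nd = np.einsum("...i,i->...", dirs, n)
        no = np.einsum("...i,i->...", origins, n) - dplane
        # keep n.(o + t d) >= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            tcross = -no / nd
        pos = nd > 0
        neg = nd < 0
        t0 = np.where(pos, np.maximum(t0, tcross), t0)
        t1 = np.where(neg, np.minimum(t1, tcross), t1)
        # rays parallel to the plane: all-or-nothing
        par_out = (nd == 0) & (no < 0)
        t1 = np.where(par_out, t0, t1)
    return np.maximum(t1 - t0, 0.0)


def forward_project(
    spec: PhantomSpec,
    geom: ProjectionGeometry,
    noise_fluence: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Analytic line-integral projections, one page per view.

    Each pixel holds the sum over primitives of attenuation times the chord
    length (mm) of the pixel's ray through the primitive, with the scene
    evaluated at the view's timestamp. With ``noise_fluence`` set, Poisson
    noise at that photon count per unsaturated ray is applied to the
    intensities and the result log-converted back to line integrals.
    """
    det = geom.detector
    nu, nv = det.nu, det.nv
    stack = np.zeros((geom.n_views, nv, nu), dtype=np.float32)
    U, V = np.meshgrid(np.arange(nu, dtype=float), np.arange(nv, dtype=float))
    pix_h = np.stack([U, V, np.ones_like(U)], axis=-1)  # (nv, nu, 3)
    for i in range(geom.n_views):
        P = geom.matrices[i]
        src = geom.source_positions[i]
        dirs = pix_h @ np.linalg.inv(P[:, :3]).T
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        # orient rays toward positive camera depth
        probe = P @ np.append(src + dirs[0, 0], 1.0)
        if probe[2] < 0:
            dirs = -dirs
        img = np.zeros((nv, nu))
        for prim in scene_at_time(spec, geom.timestamps[i]):
            img += prim.attenuation * _ray_chords(prim, src[None, None, :], dirs)
        stack[i] = img
    if noise_fluence is not None:
        if rng is None:
            raise ValueError("noise requires an explicit rng")
        counts = rng.poisson(noise_fluence * np.exp(-stack.astype(float)))
        counts = np.maximum(counts, 1)
        stack = (-np.log(counts / noise_fluence)).astype(np.float32)
    return stack


def render_volume(spec: PhantomSpec, t: float, shape, spacing, origin) -> Volume:
    """Voxelized ground-truth volume at time t.

    Voxel value = sum of attenuations of the primitives containing the voxel
    center. ``shape`` is (nx, ny, nz); array is indexed [ix, iy, iz].
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vol = np.zeros(shape, dtype=np.float32)
    for p in scene_at_time(spec, t):
        cx, cy, cz = p.center
        ax, ay, az = p.semi_axes
        inside = (
            ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
        ) <= 1.0
        if p.clip_plane is not None:
            (nx_, ny_, nz_), d = p.clip_plane
            inside &= (nx_ * X + ny_ * Y + nz_ * Z) >= d
        vol[inside] += p.attenuation
    return Volume(vol, spacing=tuple(spacing), origin=tuple(origin))
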