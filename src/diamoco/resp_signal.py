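"""1D respiration signal from per-view 3D diaphragm-top points.

Respiratory organ motion is treated as translation along the
superior-inferior (z) axis, so the signal is simply r_i = z_ref - z_i: the SI
displacement of the diaphragm top at view i relative to a reference view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RespirationSignal",
    "extract_signal",
    "smooth_signal",
    "estimate_linear_scale",
]


@dataclass
class RespirationSignal:
    """Per-view SI displacement (mm) relative to the reference view."""

    values: np.ndarray  # r_i (mm)
    z_ref: float
    ref_index: int
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps must have equal length")
        if not (0 <= self.ref_index < len(self.values)):
            raise ValueError("ref_index out of range")

    def __len__(self) -> int:
        return len(self.values)


def extract_signal(points3d, timestamps=None, ref_index: int = 0) -> RespirationSignal:
    """r_i = z_ref - z_i with z_ref the z of the point at ``ref_index``.

    Positive values mean the diaphragm sits inferior to its reference
    position (inhalation when the reference is end-exhale).
    """
    pts = np.asarray(points3d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("points3d must be a non-empty (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points3d contains missing/non-finite frames")
    if not (0 <= ref_index < pts.shape[0]):
        raise ValueError("ref_index out of range")
    z = pts[:, 2]
    z_ref = z[ref_index]
    if timestamps is None:
        timestamps = np.arange(pts.shape[0], dtype=float)
    return RespirationSignal(
        values=z_ref - z, z_ref=float(z_ref), ref_index=ref_index,
        timestamps=np.asarray(timestamps, dtype=float),
    )


def smooth_signal(signal: RespirationSignal, gauss_sigma_frames: float = 2.0) -> RespirationSignal:
    """Gaussian low-pass smoothing (discrete convolution, reflected boundary,
    unit-sum kernel)."""
    if gauss_sigma_frames < 0:
        raise ValueError("sigma must be non-negative")
    vals = (
        signal.values.copy()
        if gauss_sigma_frames == 0
        else gaussian_filter1d(signal.values, gauss_sigma_frames, mode="reflect")
    )
    return RespirationSignal(
        values=vals, z_ref=signal.z_ref, ref_index=signal.ref_index,
        timestamps=signal.timestamps.copy(),
    )


def estimate_linear_scale(diaphragm_z, target_z) -> float:
    """Least-squares slope of target displacement vs diaphragm displacement.

    Both series are taken relative to their first sample, so the fit is a
    through-the-origin regression; used to scale the diaphragm-derived signal
    to a target region (e.g. mid-lung) whose motion amplitude is smaller.
    """
    d = np.asarray(diaphragm_z, dtype=float)
    t = np.asarray(target_z, dtype=float)
    if d.shape != t.shape or d.ndim != 1 or len(d) < 2:
        raise ValueError("need two equal-length 1D series with >= 2 samples")
    dd = d - d[0]
    tt = t - t[0]
    denom = np.dot(dd, dd)
    if denom == 0:
        raise ValueError("diaphragm positions are constant; slope undefined")
    return float(np.dot(dd, tt) / denom)
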