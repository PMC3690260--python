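"""Readers/writers for projection stacks, geometry, tracks, signals, volumes,
and the end-to-end pipeline runner.

Formats: multi-page float32 TIFF for projections, JSON sidecar for geometry,
CSV for tracks and signals, MHD/NRRD (via SimpleITK) for volumes, YAML for
phantom and pipeline configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .geometry import DetectorSpec, ProjectionGeometry, make_circular_trajectory, project_point
from .reconstruction import Grid, Volume, reconstruct
from .resp_signal import extract_signal, smooth_signal
from .simulator import PhantomSpec, default_phantom, diaphragm_top_truth, forward_project
from .tracking import TrackingConfig, track_sequence, track_to_dataframe
from .triangulation import triangulate_sequence
from .evaluation import heart_crop_box, ssim_slices

log = logging.getLogger("diamoco")

__all__ = [
    "write_stack",
    "read_stack",
    "write_signal",
    "read_signal",
    "run_pipeline",
]


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path, geom: ProjectionGeometry | None = None) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    if geom is not None and stack.shape[0] != geom.n_views:
        raise ValueError(
            f"stack has {stack.shape[0]} pages but geometry expects {geom.n_views} views"
        )
    return stack


def write_signal(path, signal) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(signal)),
            "t_s": signal.timestamps,
            "r_mm": signal.values,
        }
    ).to_csv(path, index=False)


def read_signal(path):
    from .resp_signal import RespirationSignal

    df = pd.read_csv(path)
    col = "r_smoothed_mm" if "r_smoothed_mm" in df.columns else "r_mm"
    vals = df[col].to_numpy(dtype=float)
    ref = int(np.argmin(np.abs(vals)))
    return RespirationSignal(
        values=vals,
        z_ref=0.0,
        ref_index=ref,
        timestamps=df["t_s"].to_numpy(dtype=float),
    )


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run simulate -> track -> triangulate -> signal -> reconstruct -> evaluate.

    ``config`` keys (all optional, with defaults): phantom (dict or path),
    geometry (trajectory parameters), tracking, triangulation
    {offset_deg, mode}, signal {ref_index, sigma}, reconstruction
    {grid, spacing, filter}, seed. Returns a manifest with per-stage output
    paths, the seed, a config hash and stage wall times.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # validate configuration before any compute
    tr_pre = config.get("tracking", {})
    if tr_pre.get("enabled", True) and tr_pre.get("seed_point") is None:
        raise ValueError(
            "tracking is enabled but no seed point is configured "
            "(set tracking.seed_point to [u, v] or to 'auto')"
        )
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    def done(name, t0, **paths):
        dt = time.time() - t0
        log.info("stage %s finished in %.1f s", name, dt)
        manifest["stages"][name] = {"wall_s": round(dt, 3), **paths}

    # --- simulate ---------------------------------------------------------
    t0 = stage("simulate")
    ph_cfg = config.get("phantom", {})
    if isinstance(ph_cfg, (str, Path)):
        spec = PhantomSpec.from_yaml(ph_cfg)
    else:
        spec = default_phantom(
            amplitude_mm=float(ph_cfg.get("amplitude_mm", 23.0)),
            period_s=float(ph_cfg.get("period_s", 4.0)),
        )
    g = config.get("geometry", {})
    det = DetectorSpec(
        nu=int(g.get("nu", 640)),
        nv=int(g.get("nv", 480)),
        spacing_u=float(g.get("spacing", 0.616)),
        spacing_v=float(g.get("spacing", 0.616)),
    )
    geom = make_circular_trajectory(
        n_views=int(g.get("n_views", 200)),
        start_angle=float(g.get("start_angle", 0.0)),
        increment=float(g.get("increment", 1.0)),
        sod=float(g.get("sod", 800.0)),
        sdd=float(g.get("sdd", 1200.0)),
        scan_time=float(g.get("scan_time", spec.period_s)),
        detector=det,
    )
    stack = forward_project(spec, geom)
    stack_path, geom_path = out / "projections.tiff", out / "geometry.json"
    write_stack(stack_path, stack)
    geom.to_json(geom_path)
    spec.to_yaml(out / "phantom.yaml")
    done("simulate", t0, projections=str(stack_path), geometry=str(geom_path))

    # --- track ------------------------------------------------------------
    t0 = stage("track")
    tr_cfg = config.get("tracking", {})
    if tr_cfg.get("enabled", True):
        seed_uv = tr_cfg.get("seed_point")
        if seed_uv is None:
            raise ValueError(
                "tracking is enabled but no seed point is configured "
                "(set tracking.seed_point to [u, v] or to 'auto')"
            )
        if seed_uv == "auto":  # seed at the simulated apex projection
            seed_uv = project_point(geom.matrices[0], diaphragm_top_truth(spec, 0.0))
        results = track_sequence(
            stack,
            seed_uv,
            TrackingConfig(),
            rng_seed=seed,
            angles_deg=geom.angles,
        )
        track_df = track_to_dataframe(results)
        vertices = track_df[["u_vertex", "v_vertex"]].to_numpy()
    else:  # tracking disabled: use the exact simulated apex projections
        vertices = np.asarray(
            [
                project_point(
                    geom.matrices[i], diaphragm_top_truth(spec, geom.timestamps[i])
                )
                for i in range(geom.n_views)
            ]
        )
        track_df = pd.DataFrame({"u_vertex": vertices[:, 0], "v_vertex": vertices[:, 1]})
    track_path = out / "track.csv"
    track_df.to_csv(track_path, index=False)
    done("track", t0, track=str(track_path))

    # --- triangulate ------------------------------------------------------
    t0 = stage("triangulate")
    tri = config.get("triangulation", {})
    points, partners = triangulate_sequence(
        vertices,
        geom,
        offset_deg=float(tri.get("offset_deg", 90.0)),
        mode=tri.get("mode", "rectified_corrected"),
    )
    pts_path = out / "points3d.csv"
    pd.DataFrame(
        {
            "frame": np.arange(geom.n_views),
            "x": points[:, 0],
            "y": points[:, 1],
            "z": points[:, 2],
            "partner_frame": partners,
        }
    ).to_csv(pts_path, index=False)
    done("triangulate", t0, points=str(pts_path))

    # --- signal -----------------------------------------------------------
    t0 = stage("signal")
    sig_cfg = config.get("signal", {})
    sig = extract_signal(points, geom.timestamps, ref_index=int(sig_cfg.get("ref_index", 0)))
    smoothed = smooth_signal(sig, float(sig_cfg.get("sigma", 2.0)))
    sig_path = out / "signal.csv"
    pd.DataFrame(
        {
            "frame": np.arange(len(sig)),
            "t_s": sig.timestamps,
            "r_mm": sig.values,
            "r_smoothed_mm": smoothed.values,
        }
    ).to_csv(sig_path, index=False)
    done("signal", t0, signal=str(sig_path))

    # --- reconstruct ------------------------------------------------------
    t0 = stage("reconstruct")
    rc = config.get("reconstruction", {})
    grid = Grid(
        shape=(int(rc.get("grid", 128)),) * 3,
        spacing=(float(rc.get("spacing", 2.0)),) * 3,
    )
    vol_unc = reconstruct(stack, geom, model_kind="none", grid=grid)
    vol_comp = reconstruct(stack, geom, smoothed, model_kind="constant", grid=grid)
    p_unc, p_comp = out / "vol_uncompensated.mha", out / "vol_compensated.mha"
    vol_unc.write(p_unc)
    vol_comp.write(p_comp)
    done("reconstruct", t0, uncompensated=str(p_unc), compensated=str(p_comp))

    # --- evaluate ---------------------------------------------------------
    t0 = stage("evaluate")
    static = PhantomSpec(
        primitives=spec.primitives,
        amplitude_mm=0.0,
        period_s=spec.period_s,
        tracked_apex=spec.tracked_apex,
    )
    ref_stack = forward_project(static, geom)
    vol_ref = reconstruct(ref_stack, geom, model_kind="none", grid=grid)
    crop = heart_crop_box(spec, grid)
    ssim_comp = ssim_slices(vol_comp.data, vol_ref.data, crop=crop, axis="xy")
    ssim_unc = ssim_slices(vol_unc.data, vol_ref.data, crop=crop, axis="xy")
    eval_path = out / "ssim.csv"
    pd.DataFrame(
        {
            "slice": np.arange(len(ssim_comp)),
            "ssim_compensated": ssim_comp,
            "ssim_uncompensated": ssim_unc,
        }
    ).to_csv(eval_path, index=False)
    done("evaluate", t0, ssim=str(eval_path))

    manifest["hashes"] = {
        p.name: _sha(p) for p in [stack_path, track_path, pts_path, sig_path]
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
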