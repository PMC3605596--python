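"""Readers, writers and the end-to-end analysis pipeline.

Movies travel as multi-page 16-bit grayscale TIFF with a JSON sidecar
carrying the physical calibration (pixel size in um, frame interval in s);
calibration is never silently assumed.  Track tables use a flat CSV schema
with explicit units in the column names: ``track_id, frame, x_um, y_um,
intensity_counts, background``.  ``pipeline_run`` chains simulation,
detection, linking, diffusion and stoichiometry analysis into one JSON
serializable report; all randomness flows from a single seed recorded in
the report.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .simulate import GroundTruth, MovieConfig, MovieStack, simulate_movie
from .tracking import (DetectParams, LinkParams, Spot, Track, detect_movie,
                       link_tracks, tracks_to_frame)

__all__ = [
    "read_movie",
    "write_movie",
    "read_tracks",
    "write_tracks",
    "pipeline_run",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "intensity_counts", "background"]


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def write_movie(stack: MovieStack, path) -> None:
    """Write a movie as multi-page uint16 TIFF plus JSON calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.uint16))
    meta = dict(stack.meta)
    meta.update({"pixel_size_um": stack.pixel_size,
                 "frame_interval_s": stack.frame_interval})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=float))


def read_movie(path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> MovieStack:
    """Read a calibrated TIFF stack.

    Calibration comes from the JSON sidecar next to the TIFF; explicit
    ``pixel_size`` / ``frame_interval`` arguments override it.  Missing
    calibration or non-grayscale data raise errors -- units are never
    assumed.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a grayscale stack, got shape {frames.shape} "
            "(RGB/multichannel TIFF is not supported)")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            f"{path.name}: missing calibration (pixel_size_um, frame_interval_s); "
            "provide a JSON sidecar or explicit arguments")
    return MovieStack(frames, float(px), float(dt), meta=meta)


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks to the canonical CSV schema."""
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read a track CSV back into :class:`Track` objects.

    Validates the schema and that frames are strictly increasing within
    each track; malformed rows are reported with their line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in TRACK_COLUMNS:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} "
                             f"at line {int(bad[0]) + 2}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"{path}: track {tid} frames not strictly increasing")
        spots = [Spot(frame=int(r.frame), x=float(r.x_um), y=float(r.y_um),
                      integrated_intensity=float(r.intensity_counts),
                      local_background=float(r.background))
                 for r in g.itertuples()]
        tracks.append(Track(int(tid), spots))
    return tracks


def pipeline_run(config: dict) -> dict:
    """Simulate a movie, track it, and analyze mobility, density and
    stoichiometry in one deterministic pass.

    ``config`` keys: ``movie`` (MovieConfig fields), optional ``detect``
    (DetectParams fields), ``link`` (LinkParams fields), ``msd_fit_points``,
    ``max_lag``, ``step_threshold_sd``, ``seed``.  The same seed always
    produces an identical report.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    from . import density as density_mod
    from . import mobility, stoichiometry

    report: dict = {"tirftrack_version": __version__}
    try:
        movie_cfg = dict(config.get("movie", {}))
        if "seed" in config:
            movie_cfg.setdefault("rng_seed", config["seed"])
        mc = MovieConfig(**movie_cfg)
        report["seed"] = mc.rng_seed
        report["config"] = mc.to_dict()
    except (TypeError, ValueError) as e:
        raise PipelineError("configure", str(e)) from e

    try:
        stack, gt = simulate_movie(mc)
    except Exception as e:
        raise PipelineError("simulate", str(e)) from e

    try:
        spots = detect_movie(stack, DetectParams(**config.get("detect", {})))
        tracks = link_tracks(spots, LinkParams(**config.get("link", {})))
        report["n_tracks"] = len(tracks)
    except Exception as e:
        raise PipelineError("track", str(e)) from e

    try:
        area = mc.field_width * mc.field_height
        early = [len(s) for s in spots[:5]]
        est = density_mod.count_density(early, area)
        report["density"] = {"rho_um2": est.rho, "se": est.uncertainty,
                             "method": est.method,
                             "above_direct_limit": est.above_direct_limit}
    except Exception as e:
        raise PipelineError("density", str(e)) from e

    try:
        if tracks:
            curve = mobility.msd_curve(tracks, mc.frame_interval,
                                       max_lag=config.get("max_lag", 10))
            fit = mobility.fit_dlat(curve, config.get("msd_fit_points", 4))
            motion = (mobility.classify_motion(curve)
                      if len(curve.lag_s) >= 4 else "unknown")
            report["mobility"] = {"d_lat_um2_s": fit.d_lat,
                                  "intercept_um2": fit.intercept,
                                  "stderr": fit.stderr,
                                  "motion_class": motion}
    except Exception as e:
        raise PipelineError("mobility", str(e)) from e

    try:
        if tracks:
            traces = [stoichiometry.extract_intensity_trace(stack, t) for t in tracks]
            means = [np.nanmean(tr.values[tr.values > 0]) if np.any(tr.values > 0) else np.nan
                     for tr in traces]
            means = [m for m in means if np.isfinite(m)]
            if len(means) >= 100:
                hist = stoichiometry.intensity_histogram(means)
                unit = hist.mode
            else:
                unit = float(np.median(means)) if means else mc.photons_per_spot / 25.0
            thr = config.get("step_threshold_sd", 4.0)
            labels = {}
            for tr in traces:
                sm = stoichiometry.median_smooth(tr)
                sf = stoichiometry.detect_steps(sm, threshold_sd=thr)
                lab = stoichiometry.classify_trajectory(sf, unit).label
                labels[lab] = labels.get(lab, 0) + 1
            total = sum(labels.values())
            report["stoichiometry"] = {
                "unit_intensity": unit,
                "type_counts": labels,
                "type_fractions": {k: v / total for k, v in labels.items()},
            }
    except Exception as e:
        raise PipelineError("stoichiometry", str(e)) from e

    return report
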