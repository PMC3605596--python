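"""Spot detection and trajectory linking for single-molecule TIRF movies.

Diffraction-limited spots are found as local maxima above a robust noise
threshold, refined to sub-pixel precision by centroiding a background
subtracted 5x5-pixel window (500 x 500 nm^2 at the default 100 nm pixels),
and linked frame-to-frame by greedy nearest-neighbor assignment within a
maximum displacement.  At the surface densities this package targets
(<= 10 um^-2) greedy distance-ordered assignment recovers the ground-truth
identities almost always; no motion model or gap closing is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .simulate import FWHM_TO_SIGMA, MovieStack

__all__ = [
    "Spot",
    "Track",
    "DetectParams",
    "LinkParams",
    "detect_spots",
    "detect_movie",
    "link_tracks",
    "measure_fwhm",
    "default_max_displacement",
]

_WINDOW_HALF = 2  # 5x5-pixel integration window


@dataclass
class Spot:
    """One detected diffraction-limited spot."""

    frame: int
    x: float  # um, sub-pixel
    y: float  # um
    integrated_intensity: float  # background-subtracted counts over 5x5 px
    local_background: float  # counts per pixel
    saturated: bool = False


@dataclass
class Track:
    """Time-ordered sequence of spots belonging to one tracked object."""

    track_id: int
    spots: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def start_frame(self) -> int:
        return self.spots[0].frame

    @property
    def end_frame(self) -> int:
        return self.spots[-1].frame

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) positions in um."""
        return np.array([[s.x, s.y] for s in self.spots])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.integrated_intensity for s in self.spots])

    def validate(self) -> None:
        f = self.frames
        if len(f) and np.any(np.diff(f) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")


@dataclass
class DetectParams:
    """Spot detection parameters.

    threshold_sd: peak height above the frame median, in robust noise SDs.
    min_separation: minimum spot spacing in um.
    saturation_level: counts at which a pixel is considered saturated.
    """

    threshold_sd: float = 5.0
    min_separation: float = 0.4
    saturation_level: int = 65535

    def __post_init__(self):
        if self.threshold_sd <= 0 or self.min_separation <= 0:
            raise ValueError("detection parameters must be positive")


@dataclass
class LinkParams:
    """Trajectory linking parameters (displacement/gap in um/frames)."""

    max_displacement: float = 0.85
    max_gap: int = 0
    min_length: int = 5

    def __post_init__(self):
        if self.max_displacement <= 0 or self.min_length < 1 or self.max_gap < 0:
            raise ValueError("link parameters must be positive")


def default_max_displacement(d_max: float = 1.0, frame_interval: float = 0.02) -> float:
    """3 sigma of the 2D Brownian frame-to-frame step at diffusivity d_max.

    With the default D_max = 1 um^2/s, >99% of Brownian steps fall inside.
    """
    return 3.0 * np.sqrt(4.0 * d_max * frame_interval)


def _robust_noise(image: np.ndarray) -> tuple[float, float]:
    """(median, robust SD) of an image via the median absolute deviation."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, 1.4826 * mad


def detect_spots(image: np.ndarray, pixel_size: float,
                 params: DetectParams | None = None, frame: int = 0) -> list[Spot]:
    """Detect spots in one frame.

    Local maxima exceeding ``median + threshold_sd * robust_sd`` are refined
    to a sub-pixel centroid over a 5x5-pixel window after subtracting the
    local background (median of the surrounding 9x9 ring).  Integrated
    intensity is the background-subtracted sum over the window.  Coordinates
    are in um with the origin at the center of pixel (0, 0).  Saturated
    frames raise a warning and the affected spots are flagged.
    """
    params = params or DetectParams()
    image = np.asarray(image, dtype=float)
    med, sd = _robust_noise(image)
    if sd == 0:
        sd = max(np.std(image), 1e-12)
    thresh = med + params.threshold_sd * sd
    min_dist = max(1, int(round(params.min_separation / pixel_size)))
    peaks = peak_local_max(image, min_distance=min_dist,
                           threshold_abs=thresh, exclude_border=_WINDOW_HALF)
    saturated_any = False
    spots: list[Spot] = []
    for r, c in peaks:
        win = image[r - _WINDOW_HALF:r + _WINDOW_HALF + 1,
                    c - _WINDOW_HALF:c + _WINDOW_HALF + 1]
        bg = _local_background(image, r, c)
        sub = win - bg
        total = float(sub.sum())
        if total <= 0:
            continue
        sub_pos = np.clip(sub, 0, None)
        offs = np.arange(-_WINDOW_HALF, _WINDOW_HALF + 1)
        norm = sub_pos.sum()
        dy = float((sub_pos.sum(axis=1) * offs).sum() / norm)
        dx = float((sub_pos.sum(axis=0) * offs).sum() / norm)
        sat = bool(np.any(win >= params.saturation_level))
        saturated_any |= sat
        spots.append(Spot(frame=frame,
                          x=(c + dx) * pixel_size,
                          y=(r + dy) * pixel_size,
                          integrated_intensity=total,
                          local_background=float(bg),
                          saturated=sat))
    if saturated_any:
        warnings.warn("saturated pixels inside detection window; spots flagged",
                      stacklevel=2)
    return spots


def _local_background(image: np.ndarray, r: int, c: int) -> float:
    """Median of the 9x9 ring around (r, c), excluding the central 5x5."""
    h, w = image.shape
    r0, r1 = max(0, r - 4), min(h, r + 5)
    c0, c1 = max(0, c - 4), min(w, c + 5)
    outer = image[r0:r1, c0:c1]
    mask = np.ones(outer.shape, dtype=bool)
    ir0, ic0 = r - _WINDOW_HALF - r0, c - _WINDOW_HALF - c0
    mask[max(0, ir0):ir0 + 5, max(0, ic0):ic0 + 5] = False
    ring = outer[mask]
    return float(np.median(ring)) if ring.size else float(np.median(image))


def detect_movie(stack: MovieStack, params: DetectParams | None = None) -> list[list[Spot]]:
    """Run :func:`detect_spots` on every frame of a stack."""
    return [detect_spots(stack.frames[f], stack.pixel_size, params, frame=f)
            for f in range(stack.n_frames)]


def measure_fwhm(sub_image: np.ndarray, pixel_size: float) -> float:
    """FWHM (um) of an isolated spot from a radial Gaussian fit.

    Fits ``A * exp(-r^2 / (2 sigma^2)) + b`` to the sub-image around its
    brightest pixel and returns 2.3548 sigma.  Returns NaN when the fit does
    not converge or the fitted width is below the single-pixel sampling
    limit (a delta-like spike is not a resolvable PSF).
    """
    img = np.asarray(sub_image, dtype=float)
    peak = np.unravel_index(np.argmax(img), img.shape)
    yy, xx = np.indices(img.shape)

    def model(coords, amp, x0, y0, sigma, offset):
        x, y = coords
        return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset

    p0 = (img.max() - np.median(img), float(peak[1]), float(peak[0]), 1.5,
          float(np.median(img)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, (xx.ravel(), yy.ravel()), img.ravel(),
                                p0=p0, maxfev=5000)
    except RuntimeError:
        return np.nan
    sigma_px = abs(popt[3])
    if sigma_px < 0.5:  # narrower than one pixel: sub-resolution artifact
        return np.nan
    return float(sigma_px / FWHM_TO_SIGMA * pixel_size)


def link_tracks(spots_by_frame: list[list[Spot]],
                params: LinkParams | None = None) -> list[Track]:
    """Link per-frame spot lists into trajectories.

    Frame-to-frame candidate pairs within ``max_displacement`` are resolved
    greedily by ascending distance; each spot joins at most one track and no
    two spots in a frame share a track.  Unmatched spots terminate or start
    tracks; tracks shorter than ``min_length`` are discarded.  With
    ``max_gap`` > 0, a track may skip up to that many empty frames.
    """
    params = params or LinkParams()
    active: list[Track] = []
    done: list[Track] = []
    next_id = 0

    for frame_spots in spots_by_frame:
        if not frame_spots:
            continue
        frame = frame_spots[0].frame
        still, expired = [], []
        for tr in active:
            (still if frame - tr.end_frame <= params.max_gap + 1 else expired).append(tr)
        done.extend(expired)
        active = still

        if active:
            t_xy = np.array([[tr.spots[-1].x, tr.spots[-1].y] for tr in active])
            s_xy = np.array([[s.x, s.y] for s in frame_spots])
            d = np.linalg.norm(t_xy[:, None, :] - s_xy[None, :, :], axis=2)
            ti, si = np.nonzero(d <= params.max_displacement)
            order = np.argsort(d[ti, si], kind="stable")
            used_t = np.zeros(len(active), dtype=bool)
            used_s = np.zeros(len(frame_spots), dtype=bool)
            for k in order:
                a, b = ti[k], si[k]
                if used_t[a] or used_s[b]:
                    continue
                active[a].spots.append(frame_spots[b])
                used_t[a] = used_s[b] = True
        else:
            used_s = np.zeros(len(frame_spots), dtype=bool)

        for b, s in enumerate(frame_spots):
            if not used_s[b]:
                active.append(Track(next_id, [s]))
                next_id += 1

    done.extend(active)
    tracks = [t for t in done if len(t) >= params.min_length]
    tracks.sort(key=lambda t: (t.start_frame, t.track_id))
    for i, t in enumerate(tracks):
        t.track_id = i
        t.validate()
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to the canonical CSV schema."""
    rows = [(t.track_id, s.frame, s.x, s.y, s.integrated_intensity, s.local_background)
            for t in tracks for s in t.spots]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "intensity_counts", "background"])
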