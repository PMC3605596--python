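"""Synthetic TIRF movie generator with per-frame ground truth.

Emulates single-molecule TIRF recordings of fluorescently labeled membrane
receptors: Brownian diffusers at a chosen surface density, diffraction
limited integrated-Gaussian spots (~300 nm FWHM), single-step photobleaching
with exponential waiting times, a reversible monomer-dimer equilibrium
driven by 2D mass-action contact kinetics, and a small population of
immobile nonspecifically adsorbed fluorophores.  Shot noise on the signal is
Poisson; the camera background is a constant offset with Gaussian read
noise.

Every simulated quantity (positions, wrap counts, bleach state, dimer
partnerships, mobility flags) is recorded per frame in a :class:`GroundTruth`
table so downstream detection, linking, diffusion and stoichiometry
estimators can be validated against the generating process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erf

__all__ = [
    "MovieConfig",
    "MovieStack",
    "GroundTruth",
    "DimerTimeline",
    "simulate_movie",
    "simulate_dimer_kinetics",
    "FWHM_TO_SIGMA",
]

# FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian profile
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MovieConfig:
    """Parameters of one synthetic TIRF recording.

    Lengths are in micrometres, times in seconds, intensities in camera
    counts (1 photon = 1 count).  Defaults describe a perinatal-myocyte-like
    recording: receptor density ~1 um^-2, D_lat 0.15 um^2/s, 50 frames/s,
    300 nm PSF FWHM on 100 nm pixels, and a reversible dimer equilibrium
    with ~1 s dimer lifetime.
    """

    field_width: float = 20.0
    field_height: float = 20.0
    pixel_size: float = 0.1
    frame_interval: float = 0.02
    n_frames: int = 100
    receptor_density: float = 1.0
    d_lat: float = 0.15
    psf_fwhm: float = 0.3
    photons_per_spot: float = 500.0
    background_mean: float = 20.0
    background_noise_sd: float = 3.0
    bleach_rate: float = 0.1
    dimer_on_rate: float = 0.0
    dimer_off_rate: float = 1.0
    dimer_capture_radius: float = 0.1
    immobile_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "field_width", "field_height", "pixel_size", "frame_interval",
            "receptor_density", "d_lat", "psf_fwhm", "photons_per_spot",
            "background_mean", "background_noise_sd", "bleach_rate",
            "dimer_on_rate", "dimer_off_rate", "dimer_capture_radius",
            "immobile_fraction",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v!r})")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_fwhm < 2 * self.pixel_size:
            raise ValueError("psf_fwhm must be >= 2*pixel_size for resolvable sampling")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MovieStack:
    """Calibrated image stack: ``frames[t, row, col]`` in camera counts."""

    frames: np.ndarray  # (n_frames, H, W) uint16
    pixel_size: float  # um per pixel
    frame_interval: float  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


class GroundTruth:
    """Per-frame particle state history of a simulated movie.

    ``data`` has one row per (particle, frame) with columns:
    ``particle_id, frame, x_um, y_um, x_unwrapped_um, y_unwrapped_um,
    bleached, partner_id, mobile``.  Positions are wrapped into the field;
    the unwrapped columns accumulate periodic crossings so true squared
    displacements can be computed directly.
    """

    def __init__(self, data: pd.DataFrame, config: MovieConfig | None = None):
        self.data = data
        self.config = config

    def __len__(self) -> int:
        return 0 if self.data.empty else self.data["particle_id"].nunique()

    def write_csv(self, path) -> None:
        cols = ["particle_id", "frame", "x_um", "y_um", "bleached", "partner_id", "mobile"]
        self.data[cols].to_csv(path, index=False)

    def step_displacements(self, mobile_only: bool = True) -> np.ndarray:
        """Per-axis single-frame displacements (um) from unwrapped positions."""
        df = self.data
        if mobile_only:
            df = df[df["mobile"]]
        steps = []
        for _, g in df.groupby("particle_id", sort=False):
            g = g.sort_values("frame")
            steps.append(np.diff(g["x_unwrapped_um"].to_numpy()))
            steps.append(np.diff(g["y_unwrapped_um"].to_numpy()))
        return np.concatenate(steps) if steps else np.empty(0)

    def msd(self, max_lag: int, frame_interval: float, mobile_only: bool = True):
        """Ensemble/time-averaged MSD (um^2) of the true positions.

        Returns (lags_s, msd) arrays; used as the oracle for the
        detection+linking+MSD pipeline.
        """
        df = self.data
        if mobile_only:
            df = df[df["mobile"]]
        sums = np.zeros(max_lag)
        counts = np.zeros(max_lag, dtype=np.int64)
        for _, g in df.groupby("particle_id", sort=False):
            g = g.sort_values("frame")
            x = g["x_unwrapped_um"].to_numpy()
            y = g["y_unwrapped_um"].to_numpy()
            n = len(x)
            for lag in range(1, min(max_lag, n - 1) + 1):
                dx = x[lag:] - x[:-lag]
                dy = y[lag:] - y[:-lag]
                sums[lag - 1] += np.sum(dx * dx + dy * dy)
                counts[lag - 1] += n - lag
            # frames are contiguous by construction
        valid = counts > 0
        lags = (np.arange(1, max_lag + 1) * frame_interval)[valid]
        return lags, sums[valid] / counts[valid]


def _render_spots(image: np.ndarray, x_px: np.ndarray, y_px: np.ndarray,
                  photons: np.ndarray, sigma_px: float) -> None:
    """Accumulate integrated-Gaussian PSFs into ``image`` (in place).

    ``x_px``/``y_px`` are continuous pixel coordinates with the convention
    that integer coordinates lie at pixel centers.  Photon weight falling
    outside the image is clipped (lost), as for a real detector.
    """
    if len(x_px) == 0:
        return
    h, w = image.shape
    half = int(np.ceil(3.0 * sigma_px)) + 1
    offs = np.arange(-half, half + 1)
    denom = sigma_px * np.sqrt(2.0)

    cx = np.round(x_px).astype(int)
    cy = np.round(y_px).astype(int)
    # pixel i spans [i-0.5, i+0.5] around its center
    ex = 0.5 * (
        erf((cx[:, None] + offs[None, :] + 0.5 - x_px[:, None]) / denom)
        - erf((cx[:, None] + offs[None, :] - 0.5 - x_px[:, None]) / denom)
    )
    ey = 0.5 * (
        erf((cy[:, None] + offs[None, :] + 0.5 - y_px[:, None]) / denom)
        - erf((cy[:, None] + offs[None, :] - 0.5 - y_px[:, None]) / denom)
    )
    patches = photons[:, None, None] * ey[:, :, None] * ex[:, None, :]

    rows = cy[:, None] + offs[None, :]
    cols = cx[:, None] + offs[None, :]
    rr = np.broadcast_to(rows[:, :, None], patches.shape)
    cc = np.broadcast_to(cols[:, None, :], patches.shape)
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    np.add.at(image, (rr[ok], cc[ok]), patches[ok])


def simulate_movie(config: MovieConfig) -> tuple[MovieStack, GroundTruth]:
    """Simulate a TIRF movie and return the image stack plus ground truth.

    Particles are placed uniformly at ``receptor_density``; an
    ``immobile_fraction`` of them is flagged immobile (nonspecific
    adsorption).  Mobile particles take Gaussian steps with per-axis
    variance ``2*d_lat*frame_interval`` under periodic boundaries.  Each
    fluorophore photobleaches after an exponential waiting time with rate
    ``bleach_rate`` and never re-emits.  Receptor dimerization is contact
    driven: monomer pairs within ``dimer_capture_radius`` associate with the
    probability implied by the 2D mass-action rate ``dimer_on_rate``
    (um^2/s) and dissociate at ``dimer_off_rate`` (1/s); a dimer renders as
    two coincident fluorophores, i.e. one spot of double intensity until one
    partner bleaches.  Dimer chemistry is independent of bleach state.
    """
    rng = np.random.default_rng(config.rng_seed)
    area = config.field_width * config.field_height
    n = int(round(config.receptor_density * area))
    dt = config.frame_interval

    h = int(round(config.field_height / config.pixel_size))
    w = int(round(config.field_width / config.pixel_size))
    sigma_px = config.psf_fwhm * FWHM_TO_SIGMA / config.pixel_size

    if n == 0:
        frames = _render_background(rng, config, (config.n_frames, h, w))
        gt = GroundTruth(pd.DataFrame(columns=[
            "particle_id", "frame", "x_um", "y_um", "x_unwrapped_um",
            "y_unwrapped_um", "bleached", "partner_id", "mobile"]), config)
        return MovieStack(frames, config.pixel_size, dt,
                          meta={"config": config.to_dict()}), gt

    pos = rng.uniform(0.0, [config.field_width, config.field_height], size=(n, 2))
    wraps = np.zeros((n, 2))
    n_immobile = int(round(config.immobile_fraction * n))
    mobile = np.ones(n, dtype=bool)
    if n_immobile:
        mobile[rng.choice(n, size=n_immobile, replace=False)] = False

    # exponential bleach waiting times; rate 0 -> never bleaches
    if config.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / config.bleach_rate, size=n)
    else:
        t_bleach = np.full(n, np.inf)

    partner = np.full(n, -1, dtype=int)
    step_sd = np.sqrt(2.0 * config.d_lat * dt)
    r_cap = config.dimer_capture_radius
    p_on = (1.0 - np.exp(-config.dimer_on_rate * dt / (np.pi * r_cap**2))
            if config.dimer_on_rate > 0 else 0.0)
    p_off = 1.0 - np.exp(-config.dimer_off_rate * dt)
    box = np.array([config.field_width, config.field_height])

    frames = np.empty((config.n_frames, h, w), dtype=np.uint16)
    records = []
    ids = np.arange(n)

    for f in range(config.n_frames):
        t = f * dt
        bleached = t_bleach <= t

        if config.dimer_on_rate > 0 or np.any(partner >= 0):
            _update_dimers(rng, pos, wraps, partner, mobile, box,
                           r_cap, p_on, p_off)

        active = ~bleached
        expected = np.zeros((h, w))
        if np.any(active):
            _render_spots(
                expected,
                pos[active, 0] / config.pixel_size,
                pos[active, 1] / config.pixel_size,
                np.full(int(active.sum()), config.photons_per_spot),
                sigma_px,
            )
        img = rng.poisson(expected).astype(float)
        img += config.background_mean
        if config.background_noise_sd > 0:
            img += rng.normal(0.0, config.background_noise_sd, size=img.shape)
        frames[f] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

        records.append(pd.DataFrame({
            "particle_id": ids,
            "frame": f,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "x_unwrapped_um": pos[:, 0] + wraps[:, 0] * box[0],
            "y_unwrapped_um": pos[:, 1] + wraps[:, 1] * box[1],
            "bleached": bleached,
            "partner_id": partner,
            "mobile": mobile,
        }))

        # advance positions to the next frame
        steps = rng.normal(0.0, step_sd, size=(n, 2))
        steps[~mobile] = 0.0
        # dimer partners move as one unit: partner j > i copies i's step
        paired = partner >= 0
        if np.any(paired):
            lead = paired & (ids < partner)
            steps[partner[lead]] = steps[lead]
        pos += steps
        crossed = np.floor(pos / box)
        wraps += crossed
        pos -= crossed * box

    gt = GroundTruth(pd.concat(records, ignore_index=True), config)
    meta = {"config": config.to_dict(), "seed": config.rng_seed}
    return MovieStack(frames, config.pixel_size, dt, meta=meta), gt


def _render_background(rng, config: MovieConfig, shape) -> np.ndarray:
    img = np.full(shape, float(config.background_mean))
    if config.background_noise_sd > 0:
        img += rng.normal(0.0, config.background_noise_sd, size=shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def _update_dimers(rng, pos, wraps, partner, mobile, box, r_cap, p_on, p_off):
    """One kinetic step of the reversible monomer-dimer equilibrium."""
    n = len(pos)
    # dissociation first (first-order)
    paired_lead = np.flatnonzero((partner >= 0) & (np.arange(n) < partner))
    if len(paired_lead):
        split = paired_lead[rng.random(len(paired_lead)) < p_off]
        for i in split:
            j = partner[i]
            theta = rng.uniform(0.0, 2.0 * np.pi)
            d = 0.5 * r_cap * np.array([np.cos(theta), np.sin(theta)])
            for k, s in ((i, +1), (j, -1)):
                pos[k] += s * d
                crossed = np.floor(pos[k] / box)
                wraps[k] += crossed
                pos[k] -= crossed * box
            partner[i] = partner[j] = -1

    if p_on <= 0:
        return
    free = np.flatnonzero((partner < 0) & mobile)
    if len(free) < 2:
        return
    tree = cKDTree(pos[free], boxsize=box)
    pairs = tree.query_pairs(r_cap, output_type="ndarray")
    if len(pairs) == 0:
        return
    order = rng.permutation(len(pairs))
    taken = np.zeros(n, dtype=bool)
    for k in order:
        i, j = free[pairs[k]]
        if taken[i] or taken[j] or partner[i] >= 0 or partner[j] >= 0:
            continue
        if rng.random() < p_on:
            partner[i], partner[j] = j, i
            taken[i] = taken[j] = True
            mid = pos[i] + 0.5 * _min_image(pos[j] - pos[i], box)
            crossed = np.floor(mid / box)
            mid -= crossed * box
            for k2 in (i, j):
                # keep unwrapped coordinates continuous across the join
                wraps[k2] += np.round((pos[k2] - mid) / box)
                pos[k2] = mid


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


@dataclass
class DimerTimeline:
    """Output of :func:`simulate_dimer_kinetics`.

    ``counts`` holds (time_s, n_monomer, n_dimer) per step; ``dwell_times``
    are the completed dimer lifetimes in seconds.
    """

    counts: pd.DataFrame
    dwell_times: np.ndarray

    def dimer_fraction(self, discard_fraction: float = 0.25) -> float:
        """Mean fraction of particles in dimers after an equilibration burn-in."""
        df = self.counts
        start = int(len(df) * discard_fraction)
        tail = df.iloc[start:]
        denom = tail["n_monomer"] + 2 * tail["n_dimer"]
        return float((2 * tail["n_dimer"] / denom).mean()) if len(tail) else 0.0

    def mean_dwell(self) -> float:
        return float(np.mean(self.dwell_times)) if len(self.dwell_times) else np.nan


def simulate_dimer_kinetics(
    density: float,
    k_on: float,
    k_off: float,
    duration: float,
    seed: int = 0,
    *,
    d_lat: float = 0.15,
    box_side: float = 10.0,
    dt: float = 0.02,
    capture_radius: float = 0.1,
) -> DimerTimeline:
    """Particle-level reversible dimerization without imaging.

    Monomer pairs within ``capture_radius`` (um) associate with the
    per-step probability implied by the 2D mass-action on-rate ``k_on``
    (um^2/s); dimers dissociate at ``k_off`` (1/s).  Returns time-resolved
    monomer/dimer counts and the completed dimer dwell times, whose mean is
    ~1/k_off.
    """
    for name, v in (("density", density), ("k_on", k_on), ("k_off", k_off),
                    ("duration", duration)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n_steps = int(round(duration / dt))
    cols = ["time_s", "n_monomer", "n_dimer"]
    if n_steps == 0:
        return DimerTimeline(pd.DataFrame(columns=cols), np.empty(0))

    rng = np.random.default_rng(seed)
    n = int(round(density * box_side * box_side))
    box = np.array([box_side, box_side])
    pos = rng.uniform(0.0, box_side, size=(n, 2))
    wraps = np.zeros((n, 2))
    partner = np.full(n, -1, dtype=int)
    mobile = np.ones(n, dtype=bool)
    formed_at = np.full(n, np.nan)
    step_sd = np.sqrt(2.0 * d_lat * dt)
    p_on = (1.0 - np.exp(-k_on * dt / (np.pi * capture_radius**2))
            if k_on > 0 else 0.0)
    p_off = 1.0 - np.exp(-k_off * dt) if np.isfinite(k_off) else 1.0

    rows = np.empty((n_steps, 3))
    dwells = []
    ids = np.arange(n)
    for s in range(n_steps):
        t = s * dt
        before = partner.copy()
        _update_dimers(rng, pos, wraps, partner, mobile, box,
                       capture_radius, p_on, p_off)
        lead = ids < np.where(partner >= 0, partner, n)
        newly = (partner >= 0) & (before < 0) & lead
        formed_at[newly] = t
        broken = (partner < 0) & (before >= 0) & (ids < before)
        for i in np.flatnonzero(broken):
            if np.isfinite(formed_at[i]):
                dwells.append(t - formed_at[i])
            formed_at[i] = np.nan
        n_dim = int((partner >= 0).sum()) // 2
        rows[s] = (t, n - 2 * n_dim, n_dim)

        steps = rng.normal(0.0, step_sd, size=(n, 2))
        paired = partner >= 0
        if np.any(paired):
            lead_m = paired & (ids < partner)
            steps[partner[lead_m]] = steps[lead_m]
        pos += steps
        crossed = np.floor(pos / box)
        wraps += crossed
        pos -= crossed * box

    counts = pd.DataFrame(rows, columns=cols)
    counts["n_monomer"] = counts["n_monomer"].astype(int)
    counts["n_dimer"] = counts["n_dimer"].astype(int)
    return DimerTimeline(counts, np.asarray(dwells, dtype=float))
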