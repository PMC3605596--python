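"""Lateral mobility analysis: MSD curves, D_lat fits, and motion classes.

For a membrane protein undergoing free 2D Brownian motion the mean squared
displacement grows linearly with lag time, MSD = 4*D_lat*dt; a positive
intercept absorbs the static localization error (a 25 nm localization RMS
adds ~4*(0.025)^2 um^2).  Deviations from linearity discriminate directed
("flow", upward inflection) from confined ("caged", downward inflection)
motion via the anomalous exponent alpha in MSD ~ dt^alpha.  Mobility
roughly doubles per 10 degC (Q10 ~ 2), captured by a monoexponential
temperature fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .tracking import Track

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "TemperatureFit",
    "msd_curve",
    "fit_dlat",
    "classify_motion",
    "fit_temperature",
    "extrapolate_d",
]


@dataclass
class MSDCurve:
    """Ensemble/time-averaged mean squared displacement vs lag time."""

    lag_s: np.ndarray  # strictly increasing lag times (s)
    msd_um2: np.ndarray
    sd_um2: np.ndarray
    n_pairs: np.ndarray  # displacement pairs contributing per lag

    def __post_init__(self):
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.sd_um2 = np.asarray(self.sd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD must be >= 0")


@dataclass
class DiffusionEstimate:
    d_lat: float  # um^2/s
    intercept: float  # um^2
    stderr: float  # on d_lat
    fit_lags: tuple  # (first, last) lag time used, s
    motion_class: str = "free"
    clamped: bool = False


@dataclass
class TemperatureFit:
    """Monoexponential D(T) = d_ref * exp(k * (T - t_ref))."""

    d_ref: float
    k: float  # per degC
    t_ref: float

    @property
    def q10(self) -> float:
        return float(np.exp(10.0 * self.k))

    def predict(self, temperature_c):
        return self.d_ref * np.exp(self.k * (np.asarray(temperature_c) - self.t_ref))


def msd_curve(tracks: list[Track], frame_interval: float, max_lag: int = 20) -> MSDCurve:
    """Combined time- and ensemble-averaged MSD over all overlapping pairs.

    Every pair of positions in a track separated by ``lag`` frames
    contributes one squared displacement; lags with no pairs are dropped.
    """
    if not tracks:
        raise ValueError("no tracks given")
    sums = np.zeros(max_lag)
    sqsums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for tr in tracks:
        xy = tr.xy
        frames = tr.frames
        n = len(xy)
        if n < 2:
            continue
        # index by frame to honor gaps
        for i in range(n - 1):
            df = frames[i + 1:] - frames[i]
            ok = df <= max_lag
            if not np.any(ok):
                continue
            d = xy[i + 1:][ok] - xy[i]
            sq = np.sum(d * d, axis=1)
            np.add.at(sums, df[ok] - 1, sq)
            np.add.at(sqsums, df[ok] - 1, sq * sq)
            np.add.at(counts, df[ok] - 1, 1)
    valid = counts > 0
    if not np.any(valid):
        raise ValueError("no displacement pairs up to max_lag")
    mean = sums[valid] / counts[valid]
    var = np.clip(sqsums[valid] / counts[valid] - mean**2, 0, None)
    return MSDCurve(
        lag_s=np.arange(1, max_lag + 1)[valid] * frame_interval,
        msd_um2=mean,
        sd_um2=np.sqrt(var),
        n_pairs=counts[valid],
    )


def fit_dlat(curve: MSDCurve, n_fit_points: int = 4) -> DiffusionEstimate:
    """Estimate D_lat from the initial slope of the MSD curve.

    Weighted least-squares line (weights = pair counts) through the first
    ``n_fit_points`` lags; D_lat = slope / 4 with a free intercept that
    absorbs the localization-error offset.  A negative fitted slope is
    clamped to D_lat = 0 and flagged.
    """
    if n_fit_points < 2:
        raise ValueError("need >= 2 fit points")
    n = min(n_fit_points, len(curve.lag_s))
    if n < 2:
        raise ValueError("curve has fewer than 2 lags")
    x, y, w = curve.lag_s[:n], curve.msd_um2[:n], curve.n_pairs[:n].astype(float)
    W = np.diag(w)
    A = np.column_stack([x, np.ones(n)])
    cov = np.linalg.inv(A.T @ W @ A)
    beta = cov @ A.T @ W @ y
    resid = y - A @ beta
    dof = max(n - 2, 1)
    s2 = float(resid @ W @ resid) / dof
    slope_se = float(np.sqrt(s2 * cov[0, 0]))
    slope, intercept = float(beta[0]), float(beta[1])
    clamped = slope < 0
    return DiffusionEstimate(
        d_lat=max(slope, 0.0) / 4.0,
        intercept=intercept,
        stderr=slope_se / 4.0,
        fit_lags=(float(x[0]), float(x[-1])),
        clamped=clamped,
    )


def classify_motion(curve: MSDCurve, tol: float = 0.15) -> str:
    """Classify motion from the anomalous exponent alpha (log-log slope).

    alpha within 1 +/- tol -> "free"; above -> "flow" (directed transport
    adds a quadratic term); below -> "caged" (confinement saturates the
    MSD).  Non-positive MSD values are excluded from the log fit.
    """
    ok = (curve.msd_um2 > 0) & (curve.lag_s > 0)
    if ok.sum() < 4:
        raise ValueError("need >= 4 positive lags to classify motion")
    alpha = np.polyfit(np.log(curve.lag_s[ok]), np.log(curve.msd_um2[ok]), 1)[0]
    if alpha > 1 + tol:
        return "flow"
    if alpha < 1 - tol:
        return "caged"
    return "free"


def fit_temperature(temps_c, d_values, t_ref: float = 23.0) -> TemperatureFit:
    """Fit D(T) = d_ref * exp(k*(T - t_ref)) to (temperature, D) data.

    Requires >= 3 points spanning >= 10 degC; non-positive D values are
    rejected.  Q10 = exp(10 k); a doubling of mobility per 10 degC gives
    Q10 = 2.
    """
    T = np.asarray(temps_c, dtype=float)
    D = np.asarray(d_values, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diffusion coefficients must be > 0")
    if len(T) < 3 or (T.max() - T.min()) < 10:
        raise ValueError("need >= 3 temperatures spanning >= 10 degC")
    # log-linear start, then exponential least squares
    k0, logd0 = np.polyfit(T - t_ref, np.log(D), 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(lambda t, d_ref, k: d_ref * np.exp(k * (t - t_ref)),
                            T, D, p0=(np.exp(logd0), k0), maxfev=10000)
    return TemperatureFit(d_ref=float(popt[0]), k=float(popt[1]), t_ref=t_ref)


def extrapolate_d(fit: TemperatureFit, temperature_c: float) -> float:
    """Predicted D_lat (um^2/s) at a temperature, e.g. body temperature."""
    return float(fit.predict(temperature_c))
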