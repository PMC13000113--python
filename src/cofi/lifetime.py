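"""Phosphorescence-lifetime estimation from flexibly coded snapshots.

Two snapshots with nonuniform exposure schedules (a dense one for the
fast initial decay, a sparse one for the slow tail) are reconstructed
independently, their frames merged on a common clock at mid-exposure
timestamps, and a mono-exponential I(t) = baseline + A exp(-t / tau) is
fitted per pixel or per region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from cofi.encoding import TemporalSchedule
from cofi.errors import (
    InsufficientDataError,
    ShapeError,
    ValidationError,
)
from cofi.phantoms import VideoCube

TAU_BOUNDS_MS = (0.1, 100.0)


@dataclass
class DecaySeries:
    """Sampled decay curve from one pixel or one region."""

    timestamps_ms: np.ndarray
    intensities: np.ndarray
    source: str = "series"

    def __post_init__(self):
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.timestamps_ms.shape != self.intensities.shape:
            raise ValidationError("timestamps and intensities lengths differ")
        if self.timestamps_ms.size > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise ValidationError("timestamps must be strictly increasing")


@dataclass
class LifetimeFit:
    """Mono-exponential fit result."""

    tau_ms: float
    amplitude: float
    baseline: float
    r_squared: float
    converged: bool

    def summary(self) -> str:
        return (f"tau = {self.tau_ms:.4g} ms, A = {self.amplitude:.4g}, "
                f"baseline = {self.baseline:.4g}, R^2 = {self.r_squared:.4f}, "
                f"converged = {self.converged}")


@dataclass
class LifetimeMap:
    """Per-pixel lifetime map with validity mask (NaN where invalid)."""

    tau_image: np.ndarray
    amplitude_image: np.ndarray
    r_squared_image: np.ndarray
    validity_mask: np.ndarray


def merge_snapshot_series(
    recon1: VideoCube,
    schedule1: TemporalSchedule,
    recon2: VideoCube | None = None,
    schedule2: TemporalSchedule | None = None,
    gap_ms: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge reconstructed snapshots onto a common decay clock.

    Snapshot 2's schedule is offset by snapshot 1's span plus ``gap_ms``
    (the camera readout gap; default 0).  Returns (timestamps_ms, cube)
    where cube has one frame per merged timestamp.
    """
    if recon1.n_frames != schedule1.n_codes:
        raise ShapeError("recon1 frame count does not match schedule1")
    times = schedule1.midpoints_ms
    frames = recon1.frames
    if recon2 is not None:
        if schedule2 is None:
            raise ValidationError("recon2 given without schedule2")
        if recon2.grid != recon1.grid:
            raise ShapeError(
                f"reconstruction grids differ: {recon1.grid} vs {recon2.grid}")
        if recon2.n_frames != schedule2.n_codes:
            raise ShapeError("recon2 frame count does not match schedule2")
        offset = schedule1.span_ms + gap_ms
        t2 = schedule2.midpoints_ms + offset
        times = np.concatenate([times, t2])
        frames = np.concatenate([frames, recon2.frames], axis=0)
    if not np.all(np.diff(times) > 0):
        raise ValidationError("merged timestamps are not strictly increasing; "
                              "snapshot windows overlap")
    return times, frames


def _monoexp(t, baseline, amplitude, tau):
    return baseline + amplitude * np.exp(-t / tau)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Log-linear regression on baseline-subtracted values."""
    b0 = float(y.min())
    z = y - b0
    zmax = z.max()
    usable = z > 0.05 * zmax if zmax > 0 else np.zeros_like(z, dtype=bool)
    if usable.sum() >= 2 and zmax > 0:
        slope, intercept = np.polyfit(t[usable], np.log(z[usable]), 1)
        tau0 = -1.0 / slope if slope < 0 else TAU_BOUNDS_MS[1] / 2
        a0 = float(np.exp(intercept))
    else:
        tau0 = (t[-1] - t[0]) / 2 if t[-1] > t[0] else 1.0
        a0 = max(zmax, 1e-12)
    tau0 = float(np.clip(tau0, *TAU_BOUNDS_MS))
    return b0, a0, tau0


def fit_monoexponential(series: DecaySeries,
                        tau_bounds_ms: tuple[float, float] = TAU_BOUNDS_MS,
                        max_nfev: int = 200) -> LifetimeFit:
    """Least-squares mono-exponential fit with a free baseline.

    Initialised from a log-linear regression on baseline-subtracted
    values; tau is bounded.  A series with no usable dynamic range
    returns converged=False rather than raising.
    """
    t = series.timestamps_ms
    y = series.intensities
    if t.size < 4:
        raise InsufficientDataError(
            f"mono-exponential fit needs >= 4 points, got {t.size}")
    if np.ptp(y) == 0:
        return LifetimeFit(np.nan, 0.0, float(y[0]), 0.0, converged=False)
    b0, a0, tau0 = _initial_guess(t, y)
    ymax = float(np.abs(y).max())
    lo = [-ymax * 10, 0.0, tau_bounds_ms[0]]
    hi = [ymax * 10, ymax * 100 + 1e-9, tau_bounds_ms[1]]
    p0 = [np.clip(b0, lo[0], hi[0]), np.clip(a0, lo[1], hi[1]),
          np.clip(tau0, lo[2], hi[2])]
    try:
        popt, _ = curve_fit(_monoexp, t, y, p0=p0, bounds=(lo, hi),
                            max_nfev=max_nfev)
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    resid = y - _monoexp(t, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 0.0
    return LifetimeFit(tau_ms=float(popt[2]), amplitude=float(popt[1]),
                       baseline=float(popt[0]), r_squared=r2,
                       converged=converged)


def region_mean_decay(times_ms: np.ndarray, cube: np.ndarray,
                      region_mask: np.ndarray, normalize: bool = False,
                      source: str = "region") -> DecaySeries:
    """Spatial mean over a region per timestamp, optionally max-normalised."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != cube.shape[1:]:
        raise ShapeError("region mask does not match cube grid")
    if not region_mask.any():
        raise ValidationError("region mask is empty")
    series = cube[:, region_mask].mean(axis=1)
    if normalize:
        peak = series.max()
        if peak <= 0:
            raise ValidationError("cannot normalise a non-positive series")
        series = series / peak
    return DecaySeries(np.asarray(times_ms, dtype=np.float64), series, source)


def robust_background_sigma(cube: np.ndarray, background_mask: np.ndarray) -> float:
    """MAD-based sigma of background pixels across all frames."""
    vals = cube[:, np.asarray(background_mask, dtype=bool)]
    med = np.median(vals)
    return float(1.4826 * np.median(np.abs(vals - med)))


def build_lifetime_map(
    times_ms: np.ndarray,
    cube: np.ndarray,
    amplitude_threshold: float | str = "auto",
    background_mask: np.ndarray | None = None,
) -> LifetimeMap:
    """Fit a mono-exponential per pixel where the signal is strong enough.

    A pixel is fitted only where its peak intensity over time reaches
    ``amplitude_threshold``; with ``"auto"`` the threshold is 5x the
    robust (MAD) sigma of the given background region above the
    background median.  Pixels that are not fitted, or whose fit does not
    converge, are invalid (NaN in the maps).
    """
    cube = np.asarray(cube, dtype=np.float64)
    times_ms = np.asarray(times_ms, dtype=np.float64)
    if amplitude_threshold == "auto":
        if background_mask is None:
            raise ValidationError(
                "amplitude_threshold='auto' requires a background_mask")
        bg = cube[:, np.asarray(background_mask, dtype=bool)]
        thr = float(np.median(bg) + 5.0 * robust_background_sigma(cube, background_mask))
    else:
        thr = float(amplitude_threshold)
    h, w = cube.shape[1:]
    tau = np.full((h, w), np.nan)
    amp = np.full((h, w), np.nan)
    r2 = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    peak = cube.max(axis=0)
    for r, c in zip(*np.nonzero(peak >= thr)):
        fit = fit_monoexponential(
            DecaySeries(times_ms, cube[:, r, c], source=f"px({r},{c})"))
        if fit.converged:
            tau[r, c] = fit.tau_ms
            amp[r, c] = fit.amplitude
            r2[r, c] = fit.r_squared
            valid[r, c] = True
    return LifetimeMap(tau, amp, r2, valid)
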