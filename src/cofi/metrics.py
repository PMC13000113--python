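"""Evaluation metrics for reconstructed fluorescence videos.

Covers the quantitative procedures used to benchmark coded snapshot
imaging: intensity-weighted centroid tracking and linear velocity fits,
positional-error statistics against preset trajectories, mean-ratio
signal-to-background SNR, line-pair resolvability by modulation
contrast, and space-bandwidth-time-product accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from skimage.measure import profile_line

from cofi.errors import (
    InsufficientDataError,
    UndefinedCentroidError,
    UndefinedSnrError,
    ValidationError,
)


def _roi_mask(frame: np.ndarray, roi) -> np.ndarray:
    """ROI as boolean mask or (x0, y0, x1, y1) half-open pixel rectangle."""
    if roi is None:
        return np.ones(frame.shape, dtype=bool)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool:
        if roi_arr.shape != frame.shape:
            raise ValidationError("ROI mask shape does not match frame")
        return roi_arr
    x0, y0, x1, y1 = (int(v) for v in roi)
    mask = np.zeros(frame.shape, dtype=bool)
    mask[max(y0, 0):y1, max(x0, 0):x1] = True
    return mask


@dataclass
class Track:
    """Per-frame centroid trajectory of one object."""

    object_id: str
    time_ms: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    total_intensity: np.ndarray
    link_method: str = "nearest_neighbor"

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        self.y_um = np.asarray(self.y_um, dtype=np.float64)
        self.total_intensity = np.asarray(self.total_intensity, dtype=np.float64)
        if self.time_ms.size > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise ValidationError("track times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_index": np.arange(self.time_ms.size),
            "time_ms": self.time_ms,
            "object_id": self.object_id,
            "x_um": self.x_um,
            "y_um": self.y_um,
            "intensity": self.total_intensity,
        })


@dataclass
class VelocityFit:
    """Linear motion fit: per-axis slopes and the resulting speed."""

    speed_um_per_ms: float
    direction: tuple[float, float]
    slope_x: float
    slope_y: float
    stderr_x: float
    stderr_y: float
    r_squared: float


@dataclass
class SnrReport:
    """Mean-ratio SNR: mean signal intensity over mean background intensity."""

    signal_mean: float
    background_mean: float
    snr: float
    signal_roi: object = None
    background_roi: object = None


@dataclass
class ResolvabilityReport:
    """Modulation contrast of one line-pair group."""

    spacing_um: float
    contrast: float
    n_peaks_found: int
    n_peaks_expected: int
    resolvable: bool
    lp_per_mm: float


def centroid(frame: np.ndarray, roi=None, background_subtract: str | float = "min",
             pixel_pitch_um: float = 1.0) -> tuple[float, float]:
    """Intensity-weighted centroid (x_um, y_um) over an ROI.

    Background is subtracted first (the ROI minimum by default, a fixed
    level if a number is given, or ``"none"``) and negative residuals are
    clipped to zero.  Coordinates are physical, pixel centres at integer
    multiples of the pitch.
    """
    frame = np.asarray(frame, dtype=np.float64)
    mask = _roi_mask(frame, roi)
    if not mask.any():
        raise ValidationError("ROI is empty")
    vals = frame[mask]
    if background_subtract == "min":
        bg = vals.min()
    elif background_subtract in ("none", None):
        bg = 0.0
    else:
        bg = float(background_subtract)
    weights = np.clip(vals - bg, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise UndefinedCentroidError(
            "no positive mass in ROI after background subtraction")
    rows, cols = np.nonzero(mask)
    x = float(np.sum(weights * cols) / total) * pixel_pitch_um
    y = float(np.sum(weights * rows) / total) * pixel_pitch_um
    return x, y


def track_nearest_neighbor(
    cube: np.ndarray,
    times_ms: np.ndarray,
    initial_positions_um: dict[str, tuple[float, float]],
    window_radius_um: float,
    pixel_pitch_um: float = 1.0,
    background_subtract: str | float = "min",
    refine_iters: int = 3,
) -> list[Track]:
    """Greedy per-object tracking with a mean-shift-refined search window.

    Each object's centroid is measured inside a square window centred on
    its previous position, then the window is recentred on the measured
    centroid and the measurement repeated (``refine_iters`` passes),
    which removes the lag bias a fixed window would imprint on a moving
    object.  Objects must stay separated by more than the window radius
    for identities to be preserved.  A window with no mass truncates the
    track with a warning.
    """
    import warnings

    cube = np.asarray(cube, dtype=np.float64)
    times_ms = np.asarray(times_ms, dtype=np.float64)
    h, w = cube.shape[1:]
    r_px = max(int(np.ceil(window_radius_um / pixel_pitch_um)), 1)
    tracks = []
    for oid, (x0, y0) in initial_positions_um.items():
        xs, ys, its, ts = [], [], [], []
        cx, cy = x0, y0
        for k in range(cube.shape[0]):
            lost = False
            rect = None
            for _ in range(max(refine_iters, 1)):
                c_px = int(round(cx / pixel_pitch_um))
                r_px_center = int(round(cy / pixel_pitch_um))
                rect = (max(c_px - r_px, 0), max(r_px_center - r_px, 0),
                        min(c_px + r_px + 1, w), min(r_px_center + r_px + 1, h))
                try:
                    cx, cy = centroid(cube[k], rect, background_subtract,
                                      pixel_pitch_um)
                except (UndefinedCentroidError, ValidationError):
                    lost = True
                    break
            if lost:
                warnings.warn(
                    f"object {oid!r} lost at frame {k}; track truncated")
                break
            mask = _roi_mask(cube[k], rect)
            xs.append(cx)
            ys.append(cy)
            its.append(float(cube[k][mask].sum()))
            ts.append(times_ms[k])
        tracks.append(Track(oid, np.array(ts), np.array(xs), np.array(ys),
                            np.array(its)))
    return tracks


def fit_velocity(track: Track) -> VelocityFit:
    """Ordinary least-squares line per axis versus time.

    Speed is the norm of the (x, y) slope vector in um/ms; r_squared
    pools the residuals of both axes (1.0 for an exact linear track,
    including the stationary case).
    """
    n = track.time_ms.size
    if n < 3:
        raise InsufficientDataError(f"velocity fit needs >= 3 points, got {n}")
    t = track.time_ms
    fits = [stats.linregress(t, v) for v in (track.x_um, track.y_um)]
    sse = sst = 0.0
    for fit, v in zip(fits, (track.x_um, track.y_um)):
        pred = fit.intercept + fit.slope * t
        sse += float(np.sum((v - pred) ** 2))
        sst += float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse < 1e-24 else 0.0)
    sx, sy = fits[0].slope, fits[1].slope
    speed = float(np.hypot(sx, sy))
    direction = (sx / speed, sy / speed) if speed > 0 else (0.0, 0.0)
    return VelocityFit(speed_um_per_ms=speed, direction=direction,
                       slope_x=float(sx), slope_y=float(sy),
                       stderr_x=float(fits[0].stderr),
                       stderr_y=float(fits[1].stderr), r_squared=r2)


def positional_error(tracks: list[Track], ground_truth: pd.DataFrame
                     ) -> tuple[pd.DataFrame, float]:
    """Per-frame, per-axis mean (measured - preset) error, and its max.

    The ground-truth table has columns (frame_index, time_ms, object_id,
    x_um, y_um).  For each frame and axis the signed errors of all
    objects are averaged; the summary statistic is the maximum absolute
    mean error over frames and axes, in micrometres.
    """
    gt_ids = set(ground_truth["object_id"])
    track_ids = {t.object_id for t in tracks}
    missing = sorted(gt_ids.symmetric_difference(track_ids))
    if missing:
        raise ValidationError(f"unmatched object ids: {missing}")
    rows = []
    for tr in tracks:
        gt = ground_truth[ground_truth["object_id"] == tr.object_id]
        gt = gt.sort_values("frame_index")
        n = min(len(gt), tr.time_ms.size)
        for k in range(n):
            rows.append((int(gt["frame_index"].iloc[k]), tr.object_id,
                         tr.x_um[k] - float(gt["x_um"].iloc[k]),
                         tr.y_um[k] - float(gt["y_um"].iloc[k])))
    err = pd.DataFrame(rows, columns=["frame_index", "object_id", "ex_um", "ey_um"])
    per_frame = err.groupby("frame_index")[["ex_um", "ey_um"]].mean()
    per_frame = per_frame.rename(columns={"ex_um": "x", "ey_um": "y"})
    table = per_frame.reset_index().melt(
        id_vars="frame_index", var_name="axis", value_name="mean_error_um")
    max_abs = float(table["mean_error_um"].abs().max())
    return table, max_abs


def snr(image: np.ndarray, signal_roi, background_roi) -> SnrReport:
    """Ratio of the ROI mean intensities, without background subtraction."""
    image = np.asarray(image, dtype=np.float64)
    sig = _roi_mask(image, signal_roi)
    bg = _roi_mask(image, background_roi)
    if not sig.any() or not bg.any():
        raise ValidationError("SNR ROIs must be nonempty")
    if np.any(sig & bg):
        raise ValidationError("signal and background ROIs must be disjoint")
    s = float(image[sig].mean())
    b = float(image[bg].mean())
    if b <= 0:
        raise UndefinedSnrError("background mean is non-positive")
    return SnrReport(signal_mean=s, background_mean=b, snr=s / b,
                     signal_roi=signal_roi, background_roi=background_roi)


def resolvability(
    frame: np.ndarray,
    center_um: tuple[float, float],
    orientation_deg: float,
    spacing_um: float,
    n_bars: int = 3,
    pixel_pitch_um: float = 1.0,
    profile_halfwidth_um: float | None = None,
    contrast_threshold: float = 0.1,
) -> ResolvabilityReport:
    """Modulation contrast of a line-pair group from its cross-profile.

    A profile is extracted through the group centre perpendicular to the
    bar orientation (averaged over a band along the bars), peaks and
    troughs are located, and the contrast (mean_peak - mean_trough) /
    (mean_peak + mean_trough) is computed.  The group is resolvable if
    the expected number of peaks is found and contrast reaches the
    threshold; the spacing converts to 1000 / spacing lp/mm.
    """
    frame = np.asarray(frame, dtype=np.float64)
    p = pixel_pitch_um
    if profile_halfwidth_um is None:
        profile_halfwidth_um = (n_bars + 0.5) * spacing_um / 2.0
    phi = np.deg2rad(orientation_deg)
    # across-bar direction (v axis)
    vx, vy = -np.sin(phi), np.cos(phi)
    cx, cy = center_um
    start = ((cy - vy * profile_halfwidth_um) / p,
             (cx - vx * profile_halfwidth_um) / p)
    end = ((cy + vy * profile_halfwidth_um) / p,
           (cx + vx * profile_halfwidth_um) / p)
    linewidth = max(int(round(2.0 * spacing_um / p)), 1)
    prof = profile_line(frame, start, end, linewidth=linewidth, order=1,
                        mode="constant", reduce_func=np.mean)
    step_um = 2.0 * profile_halfwidth_um / max(len(prof) - 1, 1)
    if len(prof) * step_um < spacing_um:
        raise ValidationError("profile shorter than one line-pair period")
    min_dist = max(int(0.6 * spacing_um / step_um), 1)
    rng_ptp = float(np.ptp(prof))
    if rng_ptp == 0:
        return ResolvabilityReport(spacing_um, 0.0, 0, n_bars, False,
                                   1000.0 / spacing_um)
    peaks, _ = find_peaks(prof, distance=min_dist,
                          prominence=0.05 * rng_ptp)
    troughs, _ = find_peaks(-prof, distance=min_dist,
                            prominence=0.05 * rng_ptp)
    # keep troughs between the first and last peak
    if peaks.size >= 2:
        troughs = troughs[(troughs > peaks[0]) & (troughs < peaks[-1])]
    if peaks.size == 0 or troughs.size == 0:
        return ResolvabilityReport(spacing_um, 0.0, int(peaks.size), n_bars,
                                   False, 1000.0 / spacing_um)
    mp = float(prof[peaks].mean())
    mt = float(prof[troughs].mean())
    contrast = (mp - mt) / (mp + mt) if (mp + mt) > 0 else 0.0
    resolvable = bool(contrast >= contrast_threshold and peaks.size == n_bars)
    return ResolvabilityReport(spacing_um, contrast, int(peaks.size), n_bars,
                               resolvable, 1000.0 / spacing_um)


def oriented_rect_mask(grid: tuple[int, int], pixel_pitch_um: float,
                       center_um: tuple[float, float], orientation_deg: float,
                       half_length_um: float, half_width_um: float) -> np.ndarray:
    """Boolean ROI: a rectangle rotated to the bar frame.

    ``half_length_um`` extends along the bar's long axis (at
    ``orientation_deg`` to the horizontal), ``half_width_um`` across it.
    Used to isolate a single bar of a line-pair group for centroid
    measurements without capturing its neighbours.
    """
    h, w = grid
    p = pixel_pitch_um
    x = np.arange(w)[None, :] * p - center_um[0]
    y = np.arange(h)[:, None] * p - center_um[1]
    phi = np.deg2rad(orientation_deg)
    u = x * np.cos(phi) + y * np.sin(phi)
    v = -x * np.sin(phi) + y * np.cos(phi)
    return (np.abs(u) <= half_length_um) & (np.abs(v) <= half_width_um)


def spacing_to_lp_per_mm(spacing_um: float) -> float:
    """Line-pair spacing in um to spatial frequency in lp/mm."""
    if spacing_um <= 0:
        raise ValidationError("spacing must be positive")
    return 1000.0 / spacing_um


def sbtp(effective_pixels: float, frames_per_second: float) -> float:
    """Space-bandwidth-time product: resolved pixels times frame rate."""
    if effective_pixels <= 0 or frames_per_second <= 0:
        raise ValidationError("sbtp inputs must be positive")
    return effective_pixels * frames_per_second
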