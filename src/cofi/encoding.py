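"""Coded-exposure forward model for snapshot compressive imaging.

A single camera exposure integrates T scene frames, each modulated by its
own binary spatial code C_i, into one compressed measurement
Y = sum_i x_i * C_i (element-wise products).  Stacking the frames into a
vector x this is y = Phi x + n with a block-diagonal-row sensing matrix
Phi, whose key structural property is that Phi Phi^T is diagonal with
entries R = sum_i C_i^2 — the fact the closed-form ADMM x-update
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from cofi.errors import OverlapError, ShapeError, ValidationError
from cofi.phantoms import VideoCube


@dataclass
class MaskStack:
    """T binary spatial coding patterns sharing one grid."""

    codes: np.ndarray  # (T, H, W) with values in {0, 1}
    fill_fraction: float = 0.5
    seed: int | None = None
    name: str = "masks"

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3 or self.codes.shape[0] < 1:
            raise ValidationError("codes must be a (T, H, W) stack with T >= 1")
        vals = np.unique(self.codes)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be exactly 0 or 1")
        self.codes = self.codes.astype(np.float64)

    @property
    def n_codes(self) -> int:
        return self.codes.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.codes.shape[1:]


def make_mask_stack(
    shape: tuple[int, int],
    n_codes: int,
    fill_fraction: float = 0.5,
    seed: int = 0,
    name: str = "masks",
) -> MaskStack:
    """I.i.d. Bernoulli(fill_fraction) binary codes, deterministic in seed."""
    if not (0.0 < fill_fraction < 1.0):
        raise ValidationError("fill_fraction must lie strictly in (0, 1)")
    if n_codes < 1:
        raise ValidationError("n_codes must be >= 1")
    rng = np.random.default_rng(seed)
    codes = (rng.random((n_codes, *shape)) < fill_fraction).astype(np.uint8)
    return MaskStack(codes, fill_fraction=fill_fraction, seed=seed, name=name)


def make_all_on_masks(shape: tuple[int, int], n_codes: int = 1) -> MaskStack:
    """Degenerate all-ones stack (every SLM element transmitting)."""
    return MaskStack(np.ones((n_codes, *shape), dtype=np.uint8),
                     fill_fraction=1.0, seed=None, name="all_on")


@dataclass
class TemporalSchedule:
    """Per-code start times and exposure durations, in milliseconds.

    Windows must be non-overlapping and in increasing order.  The
    reference timestamp of code i for all downstream fitting and tracking
    is the mid-exposure time start_i + exposure_i / 2.
    """

    start_ms: np.ndarray
    exposure_ms: np.ndarray
    label: str = "schedule"

    def __post_init__(self):
        self.start_ms = np.asarray(self.start_ms, dtype=np.float64)
        self.exposure_ms = np.asarray(self.exposure_ms, dtype=np.float64)
        if self.start_ms.ndim != 1 or self.start_ms.size < 1:
            raise ValidationError("schedule must have at least one entry")
        if self.exposure_ms.shape != self.start_ms.shape:
            raise ValidationError("start_ms and exposure_ms lengths differ")
        if np.any(self.exposure_ms <= 0):
            raise ValidationError("exposure_ms must be positive")
        if self.start_ms.size > 1 and not np.all(np.diff(self.start_ms) > 0):
            raise ValidationError("start times must be strictly increasing")
        ends = self.start_ms + self.exposure_ms
        if np.any(ends[:-1] > self.start_ms[1:] + 1e-12):
            raise OverlapError("exposure windows overlap")

    @property
    def n_codes(self) -> int:
        return self.start_ms.size

    @property
    def midpoints_ms(self) -> np.ndarray:
        return self.start_ms + self.exposure_ms / 2.0

    @property
    def span_ms(self) -> float:
        """Total snapshot span: end of the last exposure window."""
        return float(self.start_ms[-1] + self.exposure_ms[-1])

    def shifted(self, offset_ms: float) -> "TemporalSchedule":
        return TemporalSchedule(self.start_ms + offset_ms, self.exposure_ms.copy(),
                                label=self.label)


def make_schedule(mode: str, params, label: str = "schedule") -> TemporalSchedule:
    """Build a uniform or segmented exposure schedule.

    ``uniform`` params: (n_codes, interval_ms, exposure_ms).
    ``segmented`` params: list of (n_codes, interval_ms, exposure_ms)
    segments laid out back to back.
    """
    if mode == "uniform":
        params = [tuple(params)]
    elif mode == "segmented":
        params = [tuple(p) for p in params]
    else:
        raise ValidationError(f"unknown schedule mode {mode!r}")
    starts, exposures = [], []
    t0 = 0.0
    for n_codes, interval, exposure in params:
        if exposure > interval:
            raise OverlapError(
                f"exposure {exposure} ms exceeds interval {interval} ms")
        if n_codes < 1:
            raise ValidationError("each segment needs n_codes >= 1")
        starts.extend(t0 + np.arange(n_codes) * interval)
        exposures.extend([exposure] * n_codes)
        t0 += n_codes * interval
    return TemporalSchedule(np.array(starts), np.array(exposures), label=label)


#: Library presets for the two-snapshot phosphorescence-lifetime scheme:
#: snapshot 1 samples the fast decay densely (10 codes at 300-us intervals
#: then 10 at 600-us, 150-us exposures, CR 20); snapshot 2 covers the slow
#: tail (10 codes at 1-ms intervals, 500-us exposures, CR 10).
_SCHEDULE_PRESETS: dict[str, Callable[[], TemporalSchedule]] = {
    "lifetime_snapshot1": lambda: make_schedule(
        "segmented", [(10, 0.3, 0.15), (10, 0.6, 0.15)], label="lifetime_snapshot1"),
    "lifetime_snapshot2": lambda: make_schedule(
        "uniform", (10, 1.0, 0.5), label="lifetime_snapshot2"),
}


def schedule_preset(name: str) -> TemporalSchedule:
    try:
        return _SCHEDULE_PRESETS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown schedule preset {name!r}; "
            f"available: {sorted(_SCHEDULE_PRESETS)}") from None


@dataclass
class Snapshot:
    """One compressed 2-D measurement with acquisition metadata."""

    image: np.ndarray
    mask_ref: str = "masks"
    schedule_ref: str = "schedule"
    noise_params: tuple[float, float] | None = None  # (gain, read_sigma)
    seed: int | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValidationError("snapshot image must be 2-D")
        if np.any(self.image < 0):
            raise ValidationError("snapshot image must be nonnegative")


class SensingOperator:
    """Matrix-free sensing operator Phi built from a mask stack.

    forward maps a (T, H, W) cube to the 2-D measurement; adjoint maps a
    2-D image back to a cube.  ``R`` is the diagonal of Phi Phi^T: the
    per-pixel sum over codes of C_i^2 (= sum of C_i for binary masks).
    """

    def __init__(self, masks: MaskStack):
        self.masks = masks
        self.R = masks.codes.sum(axis=0)

    @property
    def n_codes(self) -> int:
        return self.masks.n_codes

    @property
    def grid(self) -> tuple[int, int]:
        return self.masks.grid

    def forward(self, cube: np.ndarray) -> np.ndarray:
        cube = np.asarray(cube, dtype=np.float64)
        if cube.shape != self.masks.codes.shape:
            raise ShapeError(
                f"cube shape {cube.shape} does not match mask stack "
                f"{self.masks.codes.shape}")
        return np.einsum("thw,thw->hw", cube, self.masks.codes)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if y.shape != self.masks.grid:
            raise ShapeError(
                f"image shape {y.shape} does not match mask grid {self.masks.grid}")
        return self.masks.codes * y[np.newaxis, :, :]

    def dense_matrix(self) -> np.ndarray:
        """Dense Phi of shape (H*W, T*H*W); only for small oracle tests."""
        T, H, W = self.masks.codes.shape
        n = H * W
        phi = np.zeros((n, T * n))
        for i in range(T):
            phi[:, i * n:(i + 1) * n] = np.diag(self.masks.codes[i].ravel())
        return phi


def forward_encode(scene: VideoCube | np.ndarray, masks: MaskStack,
                   schedule_ref: str = "schedule") -> Snapshot:
    """Noiselessly compress a T-frame scene into one snapshot.

    The scene frames must already be the schedule-sampled intensities,
    one per code (see :func:`sample_scene_on_schedule`).
    """
    frames = scene.frames if isinstance(scene, VideoCube) else np.asarray(scene, dtype=np.float64)
    if frames.shape != masks.codes.shape:
        raise ShapeError(
            f"scene has shape {frames.shape} but mask stack is {masks.codes.shape}")
    op = SensingOperator(masks)
    return Snapshot(op.forward(frames), mask_ref=masks.name,
                    schedule_ref=schedule_ref, noise_params=None)


def add_sensor_noise(snapshot: Snapshot, gain: float = 1.0,
                     read_sigma: float = 3.0, seed: int = 0) -> Snapshot:
    """Apply shot noise and additive Gaussian read noise to a snapshot.

    image -> Poisson(image * gain) / gain + N(0, read_sigma), clipped at
    zero.  ``gain`` converts expected photoelectrons to the Poisson rate
    (gain -> infinity approaches the noiseless shot limit); read_sigma is
    in camera counts and is incurred once per snapshot — the root of the
    multiplexing advantage of coded long exposures.
    """
    if gain <= 0:
        raise ValidationError("gain must be positive")
    if read_sigma < 0:
        raise ValidationError("read_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    img = rng.poisson(snapshot.image * gain).astype(np.float64) / gain
    if read_sigma > 0:
        img += rng.normal(0.0, read_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)
    return Snapshot(img, mask_ref=snapshot.mask_ref,
                    schedule_ref=snapshot.schedule_ref,
                    noise_params=(gain, read_sigma), seed=seed)


def sample_scene_on_schedule(
    render: Callable[[Sequence[float]], VideoCube],
    schedule: TemporalSchedule,
    k_sub: int = 3,
    integrate: bool = False,
) -> VideoCube:
    """Sample a continuously renderable phantom on an exposure schedule.

    Frame i is the mean of ``k_sub`` sub-renderings at the midpoints of
    equal subdivisions of [start_i, start_i + exposure_i] — exact for
    signals linear in time, with a second-order error bound for smooth
    decays.  With ``integrate=True`` frames are scaled by the exposure
    duration (absolute integration); by default the mean intensity is
    returned so frames from nonuniform exposures stay on one scale.
    """
    if k_sub < 1:
        raise ValidationError("k_sub must be >= 1")
    sub_times = []
    for s, e in zip(schedule.start_ms, schedule.exposure_ms):
        sub_times.extend(s + (np.arange(k_sub) + 0.5) * e / k_sub)
    rendered = render(sub_times)
    frames = rendered.frames.reshape(schedule.n_codes, k_sub, *rendered.grid).mean(axis=1)
    if integrate:
        frames = frames * schedule.exposure_ms[:, None, None]
    return VideoCube(frames, schedule.midpoints_ms, rendered.pixel_pitch_um)


def effective_frame_rate_fps(schedule: TemporalSchedule) -> float:
    """Compression-ratio bookkeeping: codes per snapshot span, in fps."""
    return schedule.n_codes / (schedule.span_ms * 1e-3)
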