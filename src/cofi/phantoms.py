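"""Synthetic dynamic scenes for benchmarking snapshot compressive imaging.

All phantoms are rendered on a physical coordinate grid: positions are in
micrometres measured from the centre of the top-left pixel, x along
columns, y along rows, time in milliseconds from the start of the
snapshot exposure.  Shapes are rasterised on a supersampled grid and
mean-binned to the target grid, so sub-pixel trajectories produce
meaningful antialiased ground truth.

Intensities are expected photoelectron counts, so the camera noise model
in :mod:`cofi.encoding` applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from cofi.errors import ConfigurationError, DomainError, ValidationError

# Default detector geometry: 128 x 160 pixels at 15-um pitch gives a
# 1.92 mm x 2.40 mm field of view.
DEFAULT_GRID = (128, 160)
DEFAULT_PIXEL_PITCH_UM = 15.0


@dataclass
class VideoCube:
    """A time-ordered stack of nonnegative intensity frames.

    Used both for ground-truth scenes and for reconstructions.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames in photoelectron counts.
    timestamps_ms : ndarray, shape (T,)
        Strictly increasing frame times in milliseconds.
    pixel_pitch_um : float
        Physical pixel pitch in micrometres.
    """

    frames: np.ndarray
    timestamps_ms: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (T, H, W) array")
        if self.timestamps_ms.shape != (self.frames.shape[0],):
            raise ValidationError("one timestamp per frame required")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SceneSpec:
    """Geometry and sampling parameters of a synthetic scene.

    ``field_of_view_mm`` is (height, width) in millimetres and must agree
    with ``grid`` x ``pixel_pitch_um`` to within one pixel pitch on each
    axis.  Rendering happens on a grid finer by ``supersampling_factor``
    and is mean-binned down, which conserves flux exactly.
    """

    grid: tuple[int, int] = DEFAULT_GRID
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    field_of_view_mm: tuple[float, float] | None = None
    supersampling_factor: int = 4
    duration_ms: float = 10.0
    background_level: float = 5.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.grid
        if h < 1 or w < 1:
            raise ValidationError("grid dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValidationError("pixel_pitch_um must be positive")
        if int(self.supersampling_factor) != self.supersampling_factor or self.supersampling_factor < 1:
            raise ValidationError("supersampling_factor must be an integer >= 1")
        self.supersampling_factor = int(self.supersampling_factor)
        if self.background_level < 0:
            raise ValidationError("background_level must be nonnegative")
        if self.field_of_view_mm is None:
            self.field_of_view_mm = (
                h * self.pixel_pitch_um / 1000.0,
                w * self.pixel_pitch_um / 1000.0,
            )
        else:
            for extent_mm, n in zip(self.field_of_view_mm, self.grid):
                if abs(extent_mm * 1000.0 - n * self.pixel_pitch_um) > self.pixel_pitch_um:
                    raise ValidationError(
                        "field_of_view_mm inconsistent with grid x pixel_pitch_um "
                        f"({extent_mm} mm vs {n} px at {self.pixel_pitch_um} um)"
                    )

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) FOV extent in micrometres."""
        h, w = self.grid
        return h * self.pixel_pitch_um, w * self.pixel_pitch_um

    def supersampled_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates in um of supersampled pixel centres.

        Returns broadcastable arrays X (1, Ws) and Y (Hs, 1) such that the
        centre of target pixel (r, c) sits at (c*pitch, r*pitch).
        """
        s = self.supersampling_factor
        p = self.pixel_pitch_um
        h, w = self.grid
        xs = (np.arange(w * s) + 0.5) * (p / s) - p / 2.0
        ys = (np.arange(h * s) + 0.5) * (p / s) - p / 2.0
        return xs[np.newaxis, :], ys[:, np.newaxis]

    def bin_supersampled(self, image: np.ndarray) -> np.ndarray:
        """Mean-bin a supersampled image back to the target grid."""
        s = self.supersampling_factor
        h, w = self.grid
        return image.reshape(h, s, w, s).mean(axis=(1, 3))


@dataclass
class ObjectTrajectory:
    """A moving shaped emitter.

    ``position_function`` maps time in ms to the object centre (x_um,
    y_um).  ``shape`` is one of ``ellipse``, ``circle``, ``disk`` or
    ``bar_group``; geometry lives in the shape-specific fields.
    """

    shape: str
    position_function: Callable[[float], tuple[float, float]]
    intensity: float = 500.0
    # circle / disk
    diameter_um: float | None = None
    # ellipse
    semi_axes_um: tuple[float, float] | None = None
    orientation_deg: float = 0.0
    # bar_group
    spacing_um: float | None = None
    n_bars: int = 3
    bar_length_um: float | None = None
    time_domain_ms: tuple[float, float] = (0.0, np.inf)
    object_id: str = "obj"

    def __post_init__(self):
        if self.shape not in ("ellipse", "circle", "disk", "bar_group"):
            raise ValidationError(f"unknown shape {self.shape!r}")
        if self.intensity < 0:
            raise ValidationError("intensity must be nonnegative")
        if self.shape in ("circle", "disk"):
            if self.diameter_um is None or self.diameter_um <= 0:
                raise ValidationError("circle/disk requires diameter_um > 0")
        elif self.shape == "ellipse":
            if self.semi_axes_um is None or min(self.semi_axes_um) <= 0:
                raise ValidationError("ellipse requires positive semi_axes_um")
        elif self.shape == "bar_group":
            if self.spacing_um is None or self.spacing_um <= 0:
                raise ValidationError("bar_group requires spacing_um > 0")
            if self.n_bars < 1:
                raise ValidationError("bar_group requires n_bars >= 1")

    def position(self, t_ms: float) -> tuple[float, float]:
        lo, hi = self.time_domain_ms
        if not (lo <= t_ms <= hi):
            raise DomainError(
                f"timestamp {t_ms} ms outside trajectory domain [{lo}, {hi}] "
                f"of object {self.object_id!r}"
            )
        return self.position_function(t_ms)

    def rasterize(self, spec: SceneSpec, t_ms: float) -> np.ndarray:
        """Indicator of the object on the supersampled grid at time t."""
        cx, cy = self.position(t_ms)
        X, Y = spec.supersampled_coords()
        dx = X - cx
        dy = Y - cy
        if self.shape in ("circle", "disk"):
            r = self.diameter_um / 2.0
            return (dx * dx + dy * dy) <= r * r
        phi = np.deg2rad(self.orientation_deg)
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        if self.shape == "ellipse":
            a, b = self.semi_axes_um
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # bar_group: n_bars parallel bars, long axis along u, width
        # spacing/2 (50% duty cycle), centre-to-centre offsets along v.
        d = self.spacing_um
        length = self.bar_length_um if self.bar_length_um is not None else 4.0 * d
        offsets = (np.arange(self.n_bars) - (self.n_bars - 1) / 2.0) * d
        mask = np.zeros(u.shape, dtype=bool)
        along = np.abs(u) <= length / 2.0
        for off in offsets:
            mask |= along & (np.abs(v - off) <= d / 4.0)
        return mask

    def bar_centroids(self, t_ms: float) -> list[tuple[float, float]]:
        """Preset centroid (x_um, y_um) of each bar at time t."""
        if self.shape != "bar_group":
            raise ValidationError("bar_centroids only defined for bar_group")
        cx, cy = self.position(t_ms)
        phi = np.deg2rad(self.orientation_deg)
        d = self.spacing_um
        offsets = (np.arange(self.n_bars) - (self.n_bars - 1) / 2.0) * d
        # unit vector across the bars (the v axis in object coordinates)
        vx, vy = -np.sin(phi), np.cos(phi)
        return [(cx + off * vx, cy + off * vy) for off in offsets]


@dataclass
class DecayRegion:
    """A spatial region with mono-exponential phosphorescence decay."""

    region_mask: np.ndarray
    lifetime_ms: float
    initial_amplitude: float = 500.0
    label: str = "region"

    def __post_init__(self):
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        if self.lifetime_ms <= 0:
            raise ValidationError("lifetime_ms must be positive")
        if self.initial_amplitude < 0:
            raise ValidationError("initial_amplitude must be nonnegative")


def _check_timestamps(timestamps: Sequence[float]) -> np.ndarray:
    t = np.asarray(timestamps, dtype=np.float64)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("timestamps must be a non-empty 1-D sequence")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError("timestamps must be strictly increasing")
    return t


def render_moving_objects(
    spec: SceneSpec,
    objects: Sequence[ObjectTrajectory],
    timestamps: Sequence[float],
) -> VideoCube:
    """Render moving shaped objects, one frame per timestamp.

    Objects are rasterised on the supersampled grid and mean-binned, so
    edges are antialiased and sub-pixel motion is preserved in the
    intensity-weighted centroid.  Where objects overlap, intensities add.
    """
    if len(objects) == 0:
        raise ValidationError("objects must be non-empty")
    t = _check_timestamps(timestamps)
    frames = np.empty((t.size, *spec.grid), dtype=np.float64)
    for k, tk in enumerate(t):
        ss = np.zeros(
            (spec.grid[0] * spec.supersampling_factor,
             spec.grid[1] * spec.supersampling_factor),
            dtype=np.float64,
        )
        for obj in objects:
            ss += obj.intensity * obj.rasterize(spec, tk)
        frames[k] = spec.background_level + spec.bin_supersampled(ss)
    return VideoCube(frames, t, spec.pixel_pitch_um)


def render_bar_target(
    spec: SceneSpec,
    spacings_um: Sequence[float],
    orientation_deg: float,
    velocity_um_per_ms: tuple[float, float],
    timestamps: Sequence[float],
    group_centers_um: Sequence[tuple[float, float]] | None = None,
    intensity: float = 500.0,
    n_bars: int = 3,
) -> tuple[VideoCube, pd.DataFrame]:
    """Render translating line-pair groups and their preset bar centroids.

    Each spacing produces one group of ``n_bars`` parallel bars (width =
    spacing/2, i.e. 50% duty cycle) oriented at ``orientation_deg`` to
    the horizontal, all translating rigidly at ``velocity_um_per_ms``.

    Returns the rendered cube together with a ground-truth table with
    columns (frame_index, time_ms, object_id, x_um, y_um); object ids are
    ``g<group>_b<bar>``.
    """
    t = _check_timestamps(timestamps)
    min_spacing = 2.0 * spec.pixel_pitch_um / spec.supersampling_factor
    for d in spacings_um:
        if d < min_spacing:
            raise ConfigurationError(
                f"spacing {d} um unresolvable on the supersampled grid "
                f"(minimum {min_spacing} um)"
            )
    ext_h, ext_w = spec.extent_um
    if group_centers_um is None:
        # spread groups along the width, vertically centred
        n = len(spacings_um)
        group_centers_um = [
            (ext_w * (i + 1) / (n + 1), ext_h / 2.0) for i in range(n)
        ]
    vx, vy = velocity_um_per_ms
    objects = []
    for gi, (d, (gx, gy)) in enumerate(zip(spacings_um, group_centers_um)):
        objects.append(ObjectTrajectory(
            shape="bar_group",
            spacing_um=d,
            n_bars=n_bars,
            orientation_deg=orientation_deg,
            intensity=intensity,
            position_function=(lambda t_ms, gx=gx, gy=gy:
                               (gx + vx * t_ms, gy + vy * t_ms)),
            object_id=f"g{gi}",
        ))
    cube = render_moving_objects(spec, objects, t)
    rows = []
    for k, tk in enumerate(t):
        for obj in objects:
            for bi, (bx, by) in enumerate(obj.bar_centroids(tk)):
                rows.append((k, tk, f"{obj.object_id}_b{bi}", bx, by))
    truth = pd.DataFrame(
        rows, columns=["frame_index", "time_ms", "object_id", "x_um", "y_um"]
    )
    return cube, truth


def render_decay_phantom(
    spec: SceneSpec,
    regions: Sequence[DecayRegion],
    timestamps: Sequence[float],
    allow_overlap: bool = True,
) -> VideoCube:
    """Render a multi-species phosphorescence decay phantom.

    Pixel intensity at time t (ms after the end of the excitation pulse)
    is background + sum over regions of amplitude * exp(-t / lifetime)
    on each region's mask.  Overlapping regions add their decays, which
    emulates cross-talk between species; set ``allow_overlap=False`` to
    reject overlapping masks instead.
    """
    t = _check_timestamps(timestamps)
    if np.any(t < 0):
        raise ValidationError("decay timestamps must be >= 0")
    if len(regions) == 0:
        raise ValidationError("regions must be non-empty")
    for reg in regions:
        if reg.region_mask.shape != tuple(spec.grid):
            raise ValidationError(
                f"region {reg.label!r} mask shape {reg.region_mask.shape} "
                f"does not match scene grid {spec.grid}"
            )
    if not allow_overlap:
        cover = np.zeros(spec.grid, dtype=int)
        for reg in regions:
            cover += reg.region_mask
        if np.any(cover > 1):
            raise ValidationError("region masks overlap and allow_overlap=False")
    frames = np.full((t.size, *spec.grid), spec.background_level, dtype=np.float64)
    for reg in regions:
        decay = reg.initial_amplitude * np.exp(-t / reg.lifetime_ms)
        frames += decay[:, None, None] * reg.region_mask
    return VideoCube(frames, t, spec.pixel_pitch_um)


def disk_mask(spec: SceneSpec, center_um: tuple[float, float], radius_um: float) -> np.ndarray:
    """Boolean disk on the scene grid (pixel-centre inclusion test)."""
    h, w = spec.grid
    p = spec.pixel_pitch_um
    x = np.arange(w)[None, :] * p
    y = np.arange(h)[:, None] * p
    cx, cy = center_um
    return (x - cx) ** 2 + (y - cy) ** 2 <= radius_um ** 2


def render_microsphere_flow(
    spec: SceneSpec,
    diameter_um: float,
    speed_um_per_ms: float,
    timestamps: Sequence[float],
    start_position_um: tuple[float, float] | None = None,
    direction: tuple[float, float] = (1.0, 0.0),
    intensity: float = 500.0,
    wrap_around: bool = False,
) -> tuple[VideoCube, pd.DataFrame]:
    """Render a fluorescent microsphere translating along a channel axis.

    The sphere is projected as a uniform-brightness disk of the given
    diameter moving at constant speed along ``direction`` (unit-normalised
    internally).  Returns the cube and the preset centroid per frame.
    """
    if diameter_um <= 0:
        raise ValidationError("diameter_um must be positive")
    t = _check_timestamps(timestamps)
    ext_h, ext_w = spec.extent_um
    if start_position_um is None:
        start_position_um = (ext_w * 0.25, ext_h * 0.5)
    dnorm = float(np.hypot(*direction))
    if dnorm == 0:
        raise ValidationError("direction must be a nonzero vector")
    ux, uy = direction[0] / dnorm, direction[1] / dnorm
    x0, y0 = start_position_um
    r = diameter_um / 2.0

    positions = []
    for tk in t:
        px = x0 + speed_um_per_ms * tk * ux
        py = y0 + speed_um_per_ms * tk * uy
        if wrap_around:
            px %= ext_w
            py %= ext_h
        elif not (r <= px <= ext_w - r and r <= py <= ext_h - r):
            raise DomainError(
                f"microsphere exits the FOV at t={tk} ms "
                f"(position ({px:.2f}, {py:.2f}) um) and wrap_around is off"
            )
        positions.append((px, py))

    obj = ObjectTrajectory(
        shape="disk",
        diameter_um=diameter_um,
        intensity=intensity,
        position_function=lambda t_ms: (
            x0 + speed_um_per_ms * t_ms * ux,
            y0 + speed_um_per_ms * t_ms * uy,
        ),
        object_id="sphere",
    )
    cube = render_moving_objects(spec, [obj], t)
    truth = pd.DataFrame(
        [(k, tk, "sphere", px, py) for k, (tk, (px, py)) in enumerate(zip(t, positions))],
        columns=["frame_index", "time_ms", "object_id", "x_um", "y_um"],
    )
    return cube, truth
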