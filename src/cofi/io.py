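"""Readers and writers for the pipeline's on-disk formats.

Video cubes and snapshots travel as 32-bit float TIFF (one page per
frame) with a JSON sidecar for metadata; mask stacks as 8-bit TIFF with
values 0/255; schedules and centroid tables as CSV with fixed headers;
configs as YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from cofi.encoding import MaskStack, Snapshot, TemporalSchedule
from cofi.errors import ValidationError
from cofi.phantoms import VideoCube


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(path, cube: VideoCube) -> None:
    path = Path(path)
    tifffile.imwrite(path, cube.frames.astype(np.float32),
                     photometric='minisblack')
    meta = {
        "timestamps_ms": cube.timestamps_ms.tolist(),
        "pixel_pitch_um": cube.pixel_pitch_um,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_cube(path) -> VideoCube:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        t = np.asarray(meta["timestamps_ms"], dtype=np.float64)
        pitch = float(meta.get("pixel_pitch_um", 1.0))
    else:
        t = np.arange(frames.shape[0], dtype=np.float64)
        pitch = 1.0
    return VideoCube(frames.astype(np.float64), t, pitch)


def write_masks(path, masks: MaskStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, (masks.codes * 255).astype(np.uint8),
                     photometric='minisblack')
    meta = {"fill_fraction": masks.fill_fraction, "seed": masks.seed,
            "name": masks.name}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_masks(path) -> MaskStack:
    path = Path(path)
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[np.newaxis]
    vals = np.unique(raw)
    if not np.all(np.isin(vals, (0, 255))):
        bad = [int(v) for v in vals if v not in (0, 255)]
        raise ValidationError(
            f"mask TIFF contains non-binary values {bad}; expected 0/255")
    sidecar = _sidecar(path)
    fill, seed, name = 0.5, None, path.stem
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fill = meta.get("fill_fraction", fill)
        seed = meta.get("seed", seed)
        name = meta.get("name", name)
    return MaskStack((raw > 0).astype(np.uint8), fill_fraction=fill,
                     seed=seed, name=name)


def write_schedule(path, schedule: TemporalSchedule) -> None:
    df = pd.DataFrame({
        "code_index": np.arange(schedule.n_codes),
        "start_ms": schedule.start_ms,
        "exposure_ms": schedule.exposure_ms,
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_schedule(path, strict: bool = False,
                  label: str | None = None) -> TemporalSchedule:
    """Read a schedule CSV; unsorted rows are sorted, or rejected if strict."""
    df = pd.read_csv(path)
    expected = {"code_index", "start_ms", "exposure_ms"}
    if not expected.issubset(df.columns):
        raise ValidationError(
            f"schedule CSV must have columns {sorted(expected)}, "
            f"got {list(df.columns)}")
    if not df["start_ms"].is_monotonic_increasing:
        if strict:
            raise ValidationError("schedule rows are not sorted by start_ms")
        df = df.sort_values("start_ms")
    return TemporalSchedule(df["start_ms"].to_numpy(),
                            df["exposure_ms"].to_numpy(),
                            label=label or Path(path).stem)


def write_snapshot(path, snap: Snapshot) -> None:
    path = Path(path)
    tifffile.imwrite(path, snap.image.astype(np.float32))
    meta = {
        "mask_ref": snap.mask_ref,
        "schedule_ref": snap.schedule_ref,
        "noise_params": list(snap.noise_params) if snap.noise_params else None,
        "seed": snap.seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_snapshot(path) -> Snapshot:
    path = Path(path)
    img = tifffile.imread(path)
    sidecar = _sidecar(path)
    kwargs = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kwargs = {
            "mask_ref": meta.get("mask_ref", "masks"),
            "schedule_ref": meta.get("schedule_ref", "schedule"),
            "noise_params": tuple(meta["noise_params"]) if meta.get("noise_params") else None,
            "seed": meta.get("seed"),
        }
    return Snapshot(np.asarray(img, dtype=np.float64), **kwargs)


def write_tracks_csv(path, tracks) -> None:
    frames = [t.to_frame() for t in tracks]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=1, sort_keys=True))


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"),
                       default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
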