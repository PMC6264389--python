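"""Readers and writers for the formats the pipeline touches.

Image stacks are single-channel multi-page TIFFs; tables are CSV with a
header row.  Time is kept in seconds internally -- conversions to minutes,
hours or days happen only at the I/O edge.  Positions are exported in um;
pixel-unit tables are converted on read using the configured pixel size.
Every CLI run writes a JSON run log recording the preset and calibration
actually used, because the TIFF metadata is not trusted for timing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RunConfig",
    "ImageStack",
    "read_stack",
    "write_stack",
    "read_track_table",
    "write_track_table",
    "write_run_log",
    "FormatError",
    "SchemaError",
]

TRACK_COLUMNS = ("frame", "t_s", "x_um", "y_um")


class FormatError(ValueError):
    """Unreadable or structurally invalid input file."""


class SchemaError(ValueError):
    """A table is missing required columns or violates an ordering invariant."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run; mirrored by CLI flags."""

    stage_preset: str = "arrested_l1"
    dt: float = 10.0
    px_to_um: float = 1.0
    roi: str = "ris"
    baseline_method: str = "trace_mean"
    baseline_percentile: float = 8.0
    output_dir: str = "."
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.px_to_um <= 0:
            raise ValueError("dt and px_to_um must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON or YAML config file; keyword overrides win."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass(frozen=True)
class ImageStack:
    """A (frames, rows, columns) intensity array with its frame interval."""

    frames: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise FormatError("stack must be 3-D (frame, row, column)")
        if self.frames.shape[0] < 2:
            raise FormatError("stack must contain at least 2 frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]


def read_stack(path: str | Path, dt: float) -> ImageStack:
    """Read a single-channel multi-page TIFF in acquisition order.

    ``dt`` comes from the run configuration: acquisition timing embedded in
    TIFF metadata is not trusted.
    """
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - translate to a domain error
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise FormatError("single-frame file: velocity and frame "
                          "subtraction need at least 2 frames")
    if arr.ndim != 3:
        raise FormatError(f"expected a single-channel stack, got shape "
                          f"{arr.shape}")
    return ImageStack(frames=arr, dt=dt)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray) -> None:
    frames = stack.frames if isinstance(stack, ImageStack) else stack
    tifffile.imwrite(path, np.asarray(frames))


def read_track_table(path: str | Path, config: RunConfig) -> pd.DataFrame:
    """Read a per-frame track table and normalize it to internal units.

    Requires a ``frame`` column plus either ``t_s`` or a configured ``dt``
    to derive it, and positions either in um (``x_um, y_um``) or in pixels
    (``x_px, y_px``), converted via ``config.px_to_um``.  Time must be
    strictly increasing.
    """
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise SchemaError("track table needs a 'frame' column")
    if "t_s" not in df.columns:
        df["t_s"] = df["frame"].to_numpy(dtype=float) * config.dt
    if {"x_um", "y_um"} <= set(df.columns):
        pass
    elif {"x_px", "y_px"} <= set(df.columns):
        df["x_um"] = df["x_px"] * config.px_to_um
        df["y_um"] = df["y_px"] * config.px_to_um
    elif {"x", "y"} <= set(df.columns):
        # bare x/y are taken to be pixels, the native tracker output
        df["x_um"] = df["x"] * config.px_to_um
        df["y_um"] = df["y"] * config.px_to_um
    else:
        raise SchemaError("track table needs x/y positions "
                          "(x_um/y_um, x_px/y_px, or x/y)")
    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise SchemaError("time must be strictly increasing; "
                          "rows appear shuffled or duplicated")
    return df[[c for c in df.columns]]


def write_track_table(track: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise SchemaError(f"track table missing columns: {missing}")
    track.to_csv(path, index=False)


def write_run_log(path: str | Path, config: RunConfig, **extra) -> None:
    """Record the parameters a run actually used (preset, dt, px_to_um, seed)."""
    log = asdict(config)
    log.update(extra)
    Path(path).write_text(json.dumps(log, indent=2, default=str))
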