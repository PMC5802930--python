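"""Reading frame stacks and writing event/trajectory tables.

Coordinate convention used throughout the package: ``x`` is the column
index (the flow direction, left to right), ``y`` is the row index, origin
at the top-left corner, all pixel coordinates 0-based.  Centroids are
real-valued under the pixel-center convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "load_frames",
    "write_frames",
    "events_to_table",
    "write_events_table",
    "read_events_table",
]

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")

EVENT_COLUMNS = [
    "frame",
    "event_id",
    "cell_id",
    "x",
    "y",
    "pixels",
    "radius",
    "mean_intensity",
    "std_intensity",
]


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` holding intensities in
        arbitrary camera units.
    frame_rate
        Frames per second, if known.  ``None`` means speeds are reported in
        pixels per frame.
    pixel_size
        Physical length per pixel, if calibrated.
    """

    frames: np.ndarray
    frame_rate: Optional[float] = None
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, height, width) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a FrameStack needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    """Reduce a color image to grayscale by the channel mean."""
    img = np.asarray(img)
    if img.ndim == 3:
        # (H, W, C) with C in {3, 4}; drop an alpha channel before averaging
        if img.shape[-1] == 4:
            img = img[..., :3]
        img = img.mean(axis=-1)
    return img.astype(np.float64)


def load_frames(path: str | os.PathLike, kind: Optional[str] = None) -> FrameStack:
    """Load a frame stack from a multi-page TIFF or a directory of frames.

    Parameters
    ----------
    path
        Path to a multi-page TIFF file or a directory of single-frame
        PNG/TIFF images.
    kind
        ``"tiff_stack"`` or ``"frame_dir"``.  Inferred from the path when
        omitted (directory -> frame_dir, file -> tiff_stack).

    Frames from a directory are ordered lexicographically by filename;
    TIFF pages keep their page order.  Color frames are reduced to
    grayscale by the channel mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if kind is None:
        kind = "frame_dir" if path.is_dir() else "tiff_stack"
    if kind not in ("tiff_stack", "frame_dir"):
        raise ValueError(f"unknown kind {kind!r}")

    if kind == "tiff_stack":
        data = tifffile.imread(path)
        data = np.asarray(data)
        if data.ndim == 2:
            data = data[None]
        elif data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] not in (3, 4):
            # single color frame
            data = _to_grayscale(data)[None]
        elif data.ndim == 4:
            data = np.stack([_to_grayscale(f) for f in data])
        frames = data.astype(np.float64)
    else:
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no frames with extensions {_FRAME_EXTENSIONS} in {path}")
        frames_list = [_to_grayscale(iio.imread(p)) for p in files]
        shapes = {f.shape for f in frames_list}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        frames = np.stack(frames_list)

    if frames.shape[0] < 1:
        raise ValueError(f"no frames found in {path}")
    return FrameStack(frames=frames)


def write_frames(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a frame stack as a multi-page TIFF (float32 pages)."""
    tifffile.imwrite(Path(path), stack.frames.astype(np.float32))


def events_to_table(events: Sequence) -> pd.DataFrame:
    """Serialize events to a table, one row per event.

    Rows are sorted by ``(frame, event_id)``; unassigned cell IDs become
    missing values (empty CSV fields).
    """
    rows = []
    for ev in events:
        rows.append(
            {
                "frame": ev.frame,
                "event_id": ev.event_id,
                "cell_id": ev.cell_id,
                "x": ev.center[0],
                "y": ev.center[1],
                "pixels": ev.pixel_count,
                "radius": ev.radius,
                "mean_intensity": ev.mean_intensity,
                "std_intensity": ev.std_intensity,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["cell_id"] = df["cell_id"].astype("Int64")
    for col in ("frame", "event_id", "pixels"):
        df[col] = df[col].astype("int64")
    return df.sort_values(["frame", "event_id"], kind="stable").reset_index(drop=True)


def write_events_table(events: Sequence, path: str | os.PathLike) -> None:
    """Write the event table as CSV (header always present)."""
    df = events_to_table(events)
    df.to_csv(Path(path), index=False, float_format="%.9g")


def read_events_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an event table written by :func:`write_events_table`."""
    df = pd.read_csv(Path(path), dtype={"cell_id": "Int64"})
    return df
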