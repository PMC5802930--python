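"""Per-frame foreground identification and segmentation into events.

The camera and the microfluidic device are both fixed, so the background
of each frame is well estimated by the per-pixel temporal median of nearby
frames.  A frame is then regressed onto its estimated background (ordinary
least squares with intercept, over all pixels), which absorbs global
illumination drift; the regression residuals are fitted by a Gaussian
(sample mean and population SD) and pixels whose residual deviates by more
than ``sd_k`` standard deviations are marked foreground.  The binary mask
is cleaned by median filtering and hole filling, and its connected
components become *events* — each may be a single cell, a multi-cell
aggregate, debris, or noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.measure import label as _cc_label

from .io import FrameStack

__all__ = [
    "ForegroundConfig",
    "Event",
    "estimate_background",
    "detect_foreground",
    "extract_events",
    "segment_stack",
    "write_mask_stack",
]


@dataclass
class ForegroundConfig:
    """Parameters of foreground identification.

    window
        Number of frames over which the per-pixel temporal median is
        taken (centred on the frame of interest, clipped at the sequence
        ends).  Default 300 frames.
    sd_k
        Residual threshold in standard deviations of the regression
        residuals.  Default 3.
    median_size
        Side of the square median filter applied to the binary mask.
        Default 5 (a 5x5 window).
    min_pixels
        Minimum component size kept as an event; smaller components are
        typically debris.  Default 4 pixels.
    connectivity
        Pixel connectivity for component labelling, 4 or 8.  Default 8.
    sidedness
        ``two_sided`` keeps pixels whose residual deviates in either
        direction (cells may be brighter or darker than background);
        ``bright_only`` / ``dark_only`` keep one sign.
    """

    window: int = 300
    sd_k: float = 3.0
    median_size: int = 5
    min_pixels: int = 4
    connectivity: int = 8
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.sd_k <= 0:
            raise ValueError("sd_k must be > 0")
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be odd and >= 1")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.sidedness not in ("two_sided", "bright_only", "dark_only"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class Event:
    """One connected foreground component in one frame.

    ``coords`` holds member pixels as ``(row, col)`` pairs and
    ``intensities`` the corresponding pixel values of the original frame.
    Feature fields (centroid, pixel count, radius, intensity mean/SD) are
    derived from the members on construction.  ``cell_id`` starts
    unassigned and is filled in by the linking passes.
    """

    frame: int
    event_id: int
    coords: np.ndarray
    intensities: np.ndarray
    cell_id: Optional[int] = None
    pixel_count: int = field(init=False)
    center: tuple = field(init=False)
    radius: float = field(init=False)
    mean_intensity: float = field(init=False)
    std_intensity: float = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=np.float64).reshape(-1)
        if self.coords.shape[0] == 0:
            raise ValueError("an event needs at least one member pixel")
        if self.coords.shape[0] != self.intensities.shape[0]:
            raise ValueError("coords and intensities must have equal length")
        self.pixel_count = int(self.coords.shape[0])
        cy = float(self.coords[:, 0].mean())
        cx = float(self.coords[:, 1].mean())
        self.center = (cx, cy)
        d = np.hypot(self.coords[:, 1] - cx, self.coords[:, 0] - cy)
        self.radius = float(d.max())
        self.mean_intensity = float(self.intensities.mean())
        self.std_intensity = float(self.intensities.std())

    @classmethod
    def from_pixels(
        cls,
        frame: int,
        event_id: int,
        coords: np.ndarray,
        intensities: np.ndarray,
        cell_id: Optional[int] = None,
    ) -> "Event":
        return cls(frame=frame, event_id=event_id, coords=coords,
                   intensities=intensities, cell_id=cell_id)

    @property
    def x(self) -> float:
        return self.center[0]

    @property
    def y(self) -> float:
        return self.center[1]


def estimate_background(stack: FrameStack, t: int, window: int = 300) -> np.ndarray:
    """Per-pixel temporal median over a frame window centred at ``t``.

    The index window is clipped to the available frames at the sequence
    ends, so boundary frames use the median of fewer than ``window``
    frames rather than being discarded.
    """
    n = stack.n_frames
    if not 0 <= t < n:
        raise IndexError(f"frame index {t} out of range [0, {n})")
    lo = max(0, t - (window - 1) // 2)
    hi = min(n, t + window // 2 + 1)
    return np.median(stack.frames[lo:hi], axis=0)


def _regress(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Residuals of the OLS fit frame ~ a*background + b over all pixels."""
    x = background.ravel()
    y = frame.ravel()
    var = x.var()
    if var == 0.0:
        # constant background: slope indeterminate, intercept-only fit
        pred = np.full_like(y, y.mean())
    else:
        a = ((x - x.mean()) * (y - y.mean())).mean() / var
        b = y.mean() - a * x.mean()
        pred = a * x + b
    return (y - pred).reshape(frame.shape)


def detect_foreground(
    frame: np.ndarray, background: np.ndarray, cfg: ForegroundConfig
) -> np.ndarray:
    """Binary foreground mask of one frame given its estimated background.

    Thresholds the Gaussian-fitted regression residuals at
    ``sd_k`` standard deviations, median-filters the mask and fills
    holes (background regions not connected to the image border), so
    low-contrast interior pixels of a cell are recovered.
    """
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ValueError("frame and background must share one shape")

    resid = _regress(frame, background)
    mu = resid.mean()
    sd = resid.std()
    if sd == 0.0:
        mask = np.zeros(frame.shape, dtype=bool)
    elif cfg.sidedness == "two_sided":
        mask = np.abs(resid - mu) > cfg.sd_k * sd
    elif cfg.sidedness == "bright_only":
        mask = resid - mu > cfg.sd_k * sd
    else:
        mask = mu - resid > cfg.sd_k * sd

    if cfg.median_size > 1:
        mask = ndimage.median_filter(
            mask.astype(np.uint8), size=cfg.median_size, mode="constant", cval=0
        ).astype(bool)
    mask = ndimage.binary_fill_holes(mask)
    return mask


def extract_events(
    mask: np.ndarray, frame: np.ndarray, frame_index: int, cfg: ForegroundConfig
) -> List[Event]:
    """Segment a foreground mask into events with features.

    One event per connected component with at least ``min_pixels``
    member pixels; ``event_id`` follows the raster-scan order of each
    component's first pixel; ``cell_id`` is left unassigned.
    """
    mask = np.asarray(mask, dtype=bool)
    frame = np.asarray(frame, dtype=np.float64)
    if mask.shape != frame.shape:
        raise ValueError("mask and frame must share one shape")
    conn = 2 if cfg.connectivity == 8 else 1
    lab, n = _cc_label(mask, connectivity=conn, return_num=True)
    events: List[Event] = []
    if n == 0:
        return events
    objects = ndimage.find_objects(lab)
    eid = 0
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = lab[sl] == idx
        if int(sub.sum()) < cfg.min_pixels:
            continue
        rr, cc = np.nonzero(sub)
        coords = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        events.append(
            Event.from_pixels(
                frame=frame_index,
                event_id=eid,
                coords=coords,
                intensities=frame[coords[:, 0], coords[:, 1]],
            )
        )
        eid += 1
    return events


def segment_stack(stack: FrameStack, cfg: Optional[ForegroundConfig] = None) -> List[List[Event]]:
    """Run background estimation, foreground detection and segmentation
    on every frame, returning per-frame event lists."""
    cfg = cfg or ForegroundConfig()
    out: List[List[Event]] = []
    for t in range(stack.n_frames):
        bg = estimate_background(stack, t, cfg.window)
        mask = detect_foreground(stack.frames[t], bg, cfg)
        out.append(extract_events(mask, stack.frames[t], t, cfg))
    return out


def write_mask_stack(masks: Sequence[np.ndarray], path: str | os.PathLike) -> None:
    """Export binary masks as a multi-page TIFF for visual inspection."""
    arr = np.stack([np.asarray(m, dtype=bool) for m in masks]).astype(np.uint8) * 255
    tifffile.imwrite(Path(path), arr)
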