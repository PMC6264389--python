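"""Nucleus localization, top-k ROI intensity, dF/F, and frame subtraction.

The fluorescence readout of a labeled nucleus is the mean of the k brightest
pixels inside a small square centered on the cell body: 30 of an 11x11
square for the single RIS neuron, 500 of a 69x69 region for a pan-neuronal
head label.  Taking only the brightest pixels makes the readout robust to
the exact centering of the square and to the worm's body moving through it.

dF/F is (F - F0)/F0.  The baseline F0 is a genuine analysis choice: the
default is the full-trace mean (which forces the dF/F trace to average to
zero), with a low-percentile option (default 8th percentile) that estimates
the transient-free resting intensity and should be preferred when absolute
transient amplitudes matter.  The choice is recorded in the run log.

Frame subtraction quantifies gross movement without tracking: the activity
between consecutive frames is the count of pixels whose absolute intensity
change exceeds a noise threshold (default 3x the median absolute
frame-to-frame change of the whole stack).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack

__all__ = [
    "RoiSpec",
    "CalciumTrace",
    "ROI_PRESETS",
    "locate_nucleus",
    "roi_intensity",
    "delta_f_over_f",
    "frame_subtraction_signal",
    "extract_trace",
    "InsufficientPixelsError",
]


class InsufficientPixelsError(ValueError):
    """The edge-clipped ROI square holds fewer than k pixels."""


@dataclass(frozen=True)
class RoiSpec:
    """Top-k-of-square ROI definition."""

    square_side: int = 11
    k: int = 30

    def __post_init__(self) -> None:
        if self.square_side % 2 == 0 or self.square_side < 1:
            raise ValueError("square_side must be odd and positive")
        if not (1 <= self.k <= self.square_side ** 2):
            raise ValueError("k must satisfy 1 <= k <= square_side**2")


ROI_PRESETS = {
    "ris": RoiSpec(square_side=11, k=30),
    "panneuronal": RoiSpec(square_side=69, k=500),
}


@dataclass(frozen=True)
class CalciumTrace:
    """ROI intensity trace with its baseline and dF/F normalization."""

    t: np.ndarray
    F: np.ndarray
    f0: float
    dff: np.ndarray
    baseline_method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "F": self.F, "dff": self.dff})


def locate_nucleus(stack: ImageStack | np.ndarray,
                   search_center: tuple[int, int] | None = None,
                   blur_sigma: float = 2.0,
                   search_half: int = 15) -> pd.DataFrame:
    """Track the brightest blob frame by frame.

    Each frame is Gaussian-blurred (sigma ``blur_sigma`` px, suppressing
    single-pixel noise) and the intensity argmax taken, restricted to a
    ``(2*search_half+1)``-px box around the previous frame's position (or
    ``search_center`` on the first frame; full-frame if absent).  If the
    best value inside the box collapses to less than half the previously
    tracked peak -- the worm jumped farther than the box between frames --
    the search falls back to the full frame to re-acquire the nucleus.  A
    frame with no contrast inside its search area (blurred max equals min,
    e.g. an all-zero frame) gets ``ok=False`` and carries the previous
    position forward.

    Returns a DataFrame with columns ``frame, row, col, ok``.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a (frames, H, W) array with >= 1 frame")
    n, h, w = frames.shape
    rows = np.zeros(n, dtype=int)
    cols = np.zeros(n, dtype=int)
    ok = np.zeros(n, dtype=bool)
    prev: tuple[int, int] | None = search_center
    prev_peak: float | None = None
    for i in range(n):
        blurred = ndimage.gaussian_filter(frames[i].astype(float), blur_sigma)
        if prev is None:
            ra, rb, ca, cb = 0, h, 0, w
        else:
            ra = max(0, prev[0] - search_half)
            rb = min(h, prev[0] + search_half + 1)
            ca = max(0, prev[1] - search_half)
            cb = min(w, prev[1] + search_half + 1)
        box = blurred[ra:rb, ca:cb]
        if prev_peak is not None and box.max() < 0.5 * prev_peak:
            # track lost: the nucleus left the box; re-acquire globally
            ra, rb, ca, cb = 0, h, 0, w
            box = blurred
        if box.max() - box.min() <= 0:
            if prev is None:
                rows[i], cols[i] = h // 2, w // 2
            else:
                rows[i], cols[i] = prev
            ok[i] = False
            continue
        r, c = np.unravel_index(np.argmax(box), box.shape)
        rows[i], cols[i] = ra + r, ca + c
        ok[i] = True
        prev = (rows[i], cols[i])
        prev_peak = float(blurred[rows[i], cols[i]])
    return pd.DataFrame({"frame": np.arange(n), "row": rows, "col": cols,
                         "ok": ok})


def roi_intensity(frame: np.ndarray, center: tuple[int, int],
                  roi: RoiSpec) -> float:
    """Mean of the k brightest pixels in the ROI square around ``center``.

    The square is clipped at the image edges (worms touch chamber walls);
    it is an error only if fewer than k pixels remain.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    half = roi.square_side // 2
    r, c = int(center[0]), int(center[1])
    ra, rb = max(0, r - half), min(frame.shape[0], r + half + 1)
    ca, cb = max(0, c - half), min(frame.shape[1], c + half + 1)
    patch = frame[ra:rb, ca:cb].ravel()
    if patch.size < roi.k:
        raise InsufficientPixelsError(
            f"clipped ROI square holds {patch.size} pixels < k={roi.k}")
    top = np.partition(patch, patch.size - roi.k)[patch.size - roi.k:]
    return float(top.mean())


def delta_f_over_f(F, t=None, method: str = "trace_mean",
                   percentile: float = 8.0) -> CalciumTrace:
    """Normalize an intensity trace to dF/F = (F - F0)/F0.

    ``method`` is ``"trace_mean"`` (F0 = mean of the trace; the resulting
    dF/F has mean exactly zero) or ``"percentile"`` (F0 = the given
    percentile of the trace, default 8th, approximating the resting
    intensity).  dF/F is invariant to rescaling the raw trace.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 1 or F.size == 0:
        raise ValueError("F must be a non-empty 1-D trace")
    if np.any(F <= 0):
        raise ValueError("nonpositive intensities: upstream segmentation or "
                         "log-artifact failure")
    if method == "trace_mean":
        f0 = float(F.mean())
    elif method == "percentile":
        f0 = float(np.percentile(F, percentile))
    else:
        raise ValueError(f"unknown baseline method: {method!r}")
    t = np.arange(F.size, dtype=float) if t is None else np.asarray(t, float)
    return CalciumTrace(t=t, F=F, f0=f0, dff=(F - f0) / f0,
                        baseline_method=method)


def frame_subtraction_signal(stack: ImageStack | np.ndarray,
                             threshold: float | None = None) -> np.ndarray:
    """Changed-pixel counts between consecutive frames (length frames-1).

    A pixel counts as changed when its absolute intensity difference exceeds
    ``threshold``; the default threshold is 3x the median absolute
    frame-to-frame change over the whole stack, a plain noise floor.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need >= 2 frames")
    diffs = np.abs(np.diff(frames.astype(float), axis=0))
    if threshold is None:
        threshold = 3.0 * float(np.median(diffs))
    return (diffs > threshold).sum(axis=(1, 2)).astype(float)


def extract_trace(stack: ImageStack, roi: RoiSpec = ROI_PRESETS["ris"],
                  baseline_method: str = "trace_mean",
                  percentile: float = 8.0,
                  search_center: tuple[int, int] | None = None) -> CalciumTrace:
    """Full readout pipeline: locate_nucleus -> roi_intensity -> dF/F."""
    pos = locate_nucleus(stack, search_center=search_center)
    F = np.array([
        roi_intensity(stack.frames[i], (pos["row"][i], pos["col"][i]), roi)
        for i in range(len(stack))
    ])
    t = np.arange(len(stack)) * stack.dt
    return delta_f_over_f(F, t=t, method=baseline_method,
                          percentile=percentile)
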