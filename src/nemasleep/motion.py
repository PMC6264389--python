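"""Velocity computation and trace smoothing.

Speed is the per-frame Euclidean displacement divided by the elapsed time.
Two smoothers are provided, matching the two used for behavioral scoring:

* :func:`smooth_local_linear` -- first-degree local polynomial regression
  (lowess) with tricube weights over a fixed point count (default 25 points,
  the preset used for velocity traces before bout detection);
* :func:`running_average` -- a centered moving mean (5 points for displayed
  calcium traces, 40 points for the survival-chamber velocity variant).

Both smoothers truncate their window symmetrically at the trace boundaries,
so every output point is a weighted mean of a window centered on it.  Both
are linear operators, preserve constants, and the local-linear smoother
reproduces exactly linear traces at every point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_velocity", "smooth_local_linear", "running_average",
           "add_velocity"]


def compute_velocity(x, y, t) -> np.ndarray:
    """Per-frame speed in um/s from positions in um and times in seconds.

    ``v[i]`` is the displacement between frames ``i-1`` and ``i`` divided by
    the elapsed time ``t[i] - t[i-1]`` (so dropped frames are handled
    correctly: the speed across a gap is averaged over the true elapsed
    time).  ``v[0]`` copies ``v[1]`` so downstream bout detection receives a
    full-length trace.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (x.shape == y.shape == t.shape) or x.ndim != 1:
        raise ValueError("x, y, t must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 positions to compute velocity")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    step = np.hypot(np.diff(x), np.diff(y))
    v = np.empty_like(x)
    v[1:] = step / dt
    v[0] = v[1]
    return v


def _tricube(u: np.ndarray) -> np.ndarray:
    return (1.0 - np.clip(u, 0.0, 1.0) ** 3) ** 3


def smooth_local_linear(trace, window: int = 25) -> np.ndarray:
    """Tricube-weighted degree-1 local regression over ``window`` points.

    Even windows are reduced by one so the window is symmetric around each
    point.  At the boundaries the window shrinks symmetrically (the first
    and last points are returned unsmoothed).  Because the window and
    weights are symmetric about the evaluation point, the local-linear fit
    at the center reduces to a normalized kernel average -- but it is the
    exact weighted-least-squares solution, and reproduces any globally
    linear trace without error.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("trace must be 1-D with at least 2 points")
    if window <= 2:
        raise ValueError("window must exceed 2 points")
    if window % 2 == 0:
        window -= 1
    half = window // 2
    n = y.size
    out = np.empty(n)
    # interior: single fixed symmetric kernel, applied by convolution
    dist = np.abs(np.arange(-half, half + 1)) / (half + 1)
    kern = _tricube(dist)
    kern /= kern.sum()
    if n >= window:
        out[half:n - half] = np.convolve(y, kern, mode="valid")
    # boundaries: symmetric shrinking window
    boundary = set(range(min(half, n))) | set(range(max(0, n - half), n))
    for j in boundary:
        h = min(j, n - 1 - j, half)
        if h == 0:
            out[j] = y[j]
            continue
        seg = y[j - h:j + h + 1]
        d = np.abs(np.arange(-h, h + 1)) / (h + 1)
        w = _tricube(d)
        out[j] = float(np.sum(w * seg) / np.sum(w))
    return out


def running_average(trace, window: int) -> np.ndarray:
    """Centered moving mean with symmetric truncation at the edges.

    Window 1 is the identity.  Even windows are reduced by one to keep the
    window centered.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("trace must be 1-D")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window -= 1
    if window == 1 or y.size == 0:
        return y.copy()
    half = window // 2
    n = y.size
    out = np.empty(n)
    if n >= window:
        c = np.concatenate([[0.0], np.cumsum(y)])
        out[half:n - half] = (c[window:] - c[:-window]) / window
    boundary = set(range(min(half, n))) | set(range(max(0, n - half), n))
    for j in boundary:
        h = min(j, n - 1 - j, half)
        out[j] = y[j - h:j + h + 1].mean() if h else y[j]
    return out


def add_velocity(track: pd.DataFrame, smoothing_window: int = 25,
                 smoother: str = "lowess") -> pd.DataFrame:
    """Return a copy of a track table with ``v`` and ``v_smooth`` columns.

    ``smoother`` selects :func:`smooth_local_linear` (``"lowess"``) or
    :func:`running_average` (``"running"``).
    """
    out = track.copy()
    out["v"] = compute_velocity(track["x_um"], track["y_um"], track["t_s"])
    if smoother == "lowess":
        out["v_smooth"] = smooth_local_linear(out["v"], smoothing_window)
    elif smoother == "running":
        out["v_smooth"] = running_average(out["v"], smoothing_window)
    else:
        raise ValueError(f"unknown smoother: {smoother!r}")
    return out
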