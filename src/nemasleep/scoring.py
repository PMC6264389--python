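"""Sleep-bout detection from smoothed velocity or frame-subtraction activity.

A sleep bout is a maximal run of frames whose (smoothed) velocity is
strictly below a stage-specific cutoff and whose duration reaches the
stage's minimum.  "Below" is strict: a frame exactly at the cutoff counts
as wake.  No gap merging is applied -- two sub-threshold runs separated by
a single supra-threshold frame are scored as separate candidate bouts.

Shipped presets (smoothing points, cutoff, minimum bout):

========================  ======================  =================  ========
preset                    smoothing               cutoff             min bout
========================  ======================  =================  ========
``adult`` / ``dauer``     25-pt local linear      0.5 um/s           180 s
``arrested_l1``           25-pt local linear      3 um/s             180 s
``fed_l1``                25-pt local linear      1.2 um/s           120 s
``chamber_survival``      40-pt running average   40% of mean v      120 s
``frame_subtraction``     none                    20% of mean count  120 s
========================  ======================  =================  ========

Lethargus windows (defined by the non-pumping period) are accepted as a
user-supplied annotation, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import motion

__all__ = [
    "StageParams",
    "BoutSet",
    "PRESETS",
    "detect_bouts",
    "detect_bouts_fraction",
    "sleep_fraction",
    "score_track",
    "per_worm_chamber_sleep",
]


@dataclass(frozen=True)
class StageParams:
    """Scoring preset for one life stage.

    ``velocity_cutoff`` is in um/s when ``cutoff_is_fraction`` is False,
    otherwise a fraction of the trace mean (the survival-chamber and
    frame-subtraction variants).
    """

    name: str
    smoothing_window: int
    velocity_cutoff: float
    min_bout_s: float
    cutoff_is_fraction: bool = False
    smoother: str = "lowess"

    def __post_init__(self) -> None:
        if self.velocity_cutoff <= 0 or self.min_bout_s <= 0:
            raise ValueError("cutoff and min_bout_s must be positive")


PRESETS: dict[str, StageParams] = {
    "adult": StageParams("adult", 25, 0.5, 180.0),
    "dauer": StageParams("dauer", 25, 0.5, 180.0),
    "arrested_l1": StageParams("arrested_l1", 25, 3.0, 180.0),
    "fed_l1": StageParams("fed_l1", 25, 1.2, 120.0),
    "chamber_survival": StageParams("chamber_survival", 40, 0.4, 120.0,
                                    cutoff_is_fraction=True,
                                    smoother="running"),
    # minimum bout duration for frame-subtraction scoring is not pinned down
    # by its source; 120 s is this package's default, override as needed
    "frame_subtraction": StageParams("frame_subtraction", 1, 0.2, 120.0,
                                     cutoff_is_fraction=True,
                                     smoother="running"),
}


@dataclass(frozen=True)
class BoutSet:
    """Ordered, disjoint quiescence intervals with scoring provenance."""

    bouts: tuple[tuple[float, float], ...]
    source: str
    params: StageParams

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.bouts:
            if s < prev_end:
                raise ValueError("bouts must be sorted and disjoint")
            if e - s < self.params.min_bout_s - 1e-9:
                raise ValueError("bout shorter than the preset minimum")
            prev_end = e

    def __len__(self) -> int:
        return len(self.bouts)

    def total_time(self) -> float:
        return float(sum(e - s for s, e in self.bouts))

    def to_frame(self, worm_id: str = "") -> pd.DataFrame:
        df = pd.DataFrame(self.bouts or np.empty((0, 2)),
                          columns=["start_s", "end_s"])
        df["duration_s"] = df["end_s"] - df["start_s"]
        df.insert(0, "worm_id", worm_id)
        df["source"] = self.source
        df["preset"] = self.params.name
        return df


def _runs_below(trace: np.ndarray, cutoff: float, min_bout_s: float,
                dt: float, t0: float) -> tuple[tuple[float, float], ...]:
    below = np.asarray(trace) < cutoff
    padded = np.concatenate([[False], below, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # end index is one past the run
    bouts = []
    for a, b in zip(starts, ends):
        dur = (b - a) * dt  # frame i covers [t0 + i*dt, t0 + (i+1)*dt)
        if dur >= min_bout_s - 1e-9:
            bouts.append((t0 + a * dt, t0 + b * dt))
    return tuple(bouts)


def detect_bouts(v_smooth, params: StageParams, dt: float,
                 t0: float = 0.0) -> BoutSet:
    """Score sleep bouts on an already-smoothed velocity trace.

    Maximal runs of frames strictly below the cutoff lasting at least
    ``params.min_bout_s`` become bouts, with boundaries at the first and
    one-past-the-last sub-threshold frame.  Fraction-of-mean presets resolve
    their cutoff against the mean of this trace.
    """
    v = np.asarray(v_smooth, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("v_smooth must be a non-empty 1-D trace")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.cutoff_is_fraction:
        mean = float(v.mean())
        if mean <= 0:
            raise ValueError("all-zero trace: fraction-of-mean cutoff "
                             "undefined")
        cutoff = params.velocity_cutoff * mean
    else:
        cutoff = params.velocity_cutoff
    return BoutSet(_runs_below(v, cutoff, params.min_bout_s, dt, t0),
                   source="velocity", params=params)


def detect_bouts_fraction(activity, fraction: float, min_bout_s: float,
                          dt: float, t0: float = 0.0) -> BoutSet:
    """Score quiescence on an activity trace with a fraction-of-mean cutoff.

    Used for frame-subtraction scoring (fraction 0.2 of the mean changed-
    pixel count) and for the survival-chamber velocity variant (0.4 of the
    mean velocity).
    """
    params = StageParams("fraction", 1, fraction, min_bout_s,
                         cutoff_is_fraction=True, smoother="running")
    bs = detect_bouts(activity, params, dt, t0=t0)
    return replace(bs, source="frame_subtraction")


def sleep_fraction(bouts: BoutSet | tuple, window: tuple[float, float]) -> float:
    """Fraction of ``window`` covered by sleep bouts (interval intersection)."""
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive length")
    ivals = bouts.bouts if isinstance(bouts, BoutSet) else tuple(bouts)
    covered = sum(max(0.0, min(e, w1) - max(s, w0)) for s, e in ivals)
    return covered / (w1 - w0)


def score_track(track: pd.DataFrame, params: StageParams,
                ) -> tuple[BoutSet, pd.DataFrame]:
    """Smooth a track's velocity per the preset and detect bouts.

    Returns the bout set and the track augmented with ``v``/``v_smooth``.
    """
    t = track["t_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t)))
    tr = motion.add_velocity(track, params.smoothing_window, params.smoother)
    bouts = detect_bouts(tr["v_smooth"].to_numpy(), params, dt, t0=float(t[0]))
    return bouts, tr


@dataclass(frozen=True)
class ChamberSleepResult:
    sleep_fraction: float
    hours_covered: float
    excluded: bool
    bouts: BoutSet


def per_worm_chamber_sleep(track: pd.DataFrame,
                           params: StageParams = PRESETS["chamber_survival"],
                           window_s: tuple[float, float] = (2 * 86400.0,
                                                            4 * 86400.0),
                           min_hours: float = 35.0) -> ChamberSleepResult:
    """Per-worm sleep fraction in the chamber-survival assay.

    The fraction is computed over the part of ``window_s`` (day 2 to day 4
    of starvation by default) the footage actually covers; a worm with less
    than ``min_hours`` of coverage is flagged ``excluded`` and should be
    dropped from downstream sleep-survival fits.
    """
    t = track["t_s"].to_numpy(dtype=float)
    sel = track[(t >= window_s[0]) & (t < window_s[1])]
    if len(sel) < 2:
        empty = BoutSet((), "velocity", params)
        return ChamberSleepResult(0.0, 0.0, True, empty)
    tsel = sel["t_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(tsel)))
    hours = (tsel[-1] - tsel[0] + dt) / 3600.0
    bouts, _ = score_track(sel.reset_index(drop=True), params)
    frac = sleep_fraction(bouts, (tsel[0], tsel[-1] + dt))
    return ChamberSleepResult(frac, hours, hours < min_hours, bouts)
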