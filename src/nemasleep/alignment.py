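"""Event-triggered averaging around sleep-bout onsets.

Calcium (dF/F) and velocity traces are aligned to each accepted bout onset
on a common grid from 15 min before to 30 min after onset.  To keep the
pre-onset baseline flat, an onset is rejected when any other bout intrudes
into its 15-min pre-window; onsets whose window is not fully covered by the
recording are dropped and counted separately.  The onset contrast compares
the mean dF/F in the 5 min before versus the 5 min after onset, averaged
per worm first, with the paired Wilcoxon signed-rank test across worms.

Display smoothing (a 5-point running average) is applied only when
exporting per-animal traces, never before statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import motion, stats
from .scoring import BoutSet

__all__ = ["AlignedEnsemble", "align_to_onsets", "build_ensemble",
           "onset_contrast", "OnsetContrast"]

PRE_S = 900.0
POST_S = 1800.0
CONTRAST_S = 300.0


@dataclass(frozen=True)
class AlignedEnsemble:
    """Bout-onset-aligned rows of dF/F and velocity on a shared grid."""

    t_rel: np.ndarray                  # seconds relative to onset
    dff: np.ndarray                    # (n_rows, len(t_rel))
    v: np.ndarray
    worm_ids: tuple[str, ...]
    onset_times: tuple[float, ...]
    n_excluded: int                    # onsets with a bout in the pre-window
    n_partial: int                     # onsets without full window coverage

    @property
    def n_rows(self) -> int:
        return len(self.worm_ids)

    def mean_dff(self) -> np.ndarray:
        return self.dff.mean(axis=0)

    def to_frame(self, display_smooth: bool = False) -> pd.DataFrame:
        """Long-format export; optional 5-point display smoothing of dF/F."""
        rows = []
        for i, (w, onset) in enumerate(zip(self.worm_ids, self.onset_times)):
            dff = self.dff[i]
            if display_smooth:
                dff = motion.running_average(dff, 5)
            rows.append(pd.DataFrame({
                "onset_id": i, "worm_id": w, "onset_s": onset,
                "t_rel_s": self.t_rel, "dff": dff, "v": self.v[i],
            }))
        if not rows:
            return pd.DataFrame(columns=["onset_id", "worm_id", "onset_s",
                                         "t_rel_s", "dff", "v"])
        return pd.concat(rows, ignore_index=True)


def align_to_onsets(track: pd.DataFrame, bouts: BoutSet,
                    worm_id: str = "w0",
                    pre_s: float = PRE_S, post_s: float = POST_S,
                    dff_column: str = "dff",
                    v_column: str = "v_smooth") -> AlignedEnsemble:
    """Align one worm's traces to its accepted sleep-bout onsets.

    The track must carry the dF/F and velocity columns (see
    :func:`nemasleep.roi.delta_f_over_f` and
    :func:`nemasleep.motion.add_velocity`).  An empty ensemble (zero rows)
    is a valid result, not an error.
    """
    t = track["t_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    t_rel = np.arange(-n_pre, n_post + 1) * dt
    dff = track[dff_column].to_numpy(dtype=float)
    v = track[v_column].to_numpy(dtype=float)

    rows_dff, rows_v, onsets_kept = [], [], []
    n_excluded = n_partial = 0
    for onset, _end in bouts.bouts:
        intruder = any(e > onset - pre_s and s < onset
                       for s, e in bouts.bouts if s < onset)
        if intruder:
            n_excluded += 1
            continue
        i0 = int(round((onset - t[0]) / dt))
        a, b = i0 - n_pre, i0 + n_post + 1
        if a < 0 or b > t.size:
            n_partial += 1
            continue
        rows_dff.append(dff[a:b])
        rows_v.append(v[a:b])
        onsets_kept.append(onset)
    shape = (len(rows_dff), t_rel.size)
    return AlignedEnsemble(
        t_rel=t_rel,
        dff=np.array(rows_dff).reshape(shape),
        v=np.array(rows_v).reshape(shape),
        worm_ids=tuple([worm_id] * len(rows_dff)),
        onset_times=tuple(onsets_kept),
        n_excluded=n_excluded,
        n_partial=n_partial,
    )


def build_ensemble(per_worm: dict[str, tuple[pd.DataFrame, BoutSet]],
                   **kwargs) -> AlignedEnsemble:
    """Stack :func:`align_to_onsets` results from several worms."""
    parts = [align_to_onsets(track, bouts, worm_id=w, **kwargs)
             for w, (track, bouts) in per_worm.items()]
    if not parts:
        raise ValueError("no worms supplied")
    t_rel = parts[0].t_rel
    return AlignedEnsemble(
        t_rel=t_rel,
        dff=np.vstack([p.dff for p in parts]),
        v=np.vstack([p.v for p in parts]),
        worm_ids=tuple(w for p in parts for w in p.worm_ids),
        onset_times=tuple(o for p in parts for o in p.onset_times),
        n_excluded=sum(p.n_excluded for p in parts),
        n_partial=sum(p.n_partial for p in parts),
    )


@dataclass(frozen=True)
class OnsetContrast:
    """Per-worm pre/post dF/F means around bout onset and the paired test."""

    per_worm: pd.DataFrame             # worm_id, pre_mean, post_mean, delta
    delta_mean: float
    delta_sem: float
    p: float | None
    n_worms: int


def onset_contrast(ensemble: AlignedEnsemble,
                   window_s: float = CONTRAST_S) -> OnsetContrast:
    """Compare mean dF/F in [-window, 0) vs [0, +window] around onset.

    Rows are averaged within each worm first (n = worms, the reporting
    convention for these experiments); the paired Wilcoxon signed-rank test
    runs across worms.  With fewer than two worms the pairs are still
    returned but the test is undefined (``p=None``).
    """
    pre_mask = (ensemble.t_rel >= -window_s) & (ensemble.t_rel < 0)
    post_mask = (ensemble.t_rel >= 0) & (ensemble.t_rel <= window_s)
    recs = []
    for w in dict.fromkeys(ensemble.worm_ids):
        rows = np.array([i for i, wid in enumerate(ensemble.worm_ids)
                         if wid == w])
        pre = float(ensemble.dff[rows][:, pre_mask].mean())
        post = float(ensemble.dff[rows][:, post_mask].mean())
        recs.append((w, pre, post, post - pre))
    per_worm = pd.DataFrame(recs, columns=["worm_id", "pre_mean",
                                           "post_mean", "delta"])
    n = len(per_worm)
    if n == 0:
        return OnsetContrast(per_worm, float("nan"), float("nan"), None, 0)
    deltas = per_worm["delta"].to_numpy()
    sem = float(np.std(deltas, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    p = None
    if n >= 2:
        p = stats.wilcoxon_signed_rank(per_worm["post_mean"],
                                       per_worm["pre_mean"]).p
    return OnsetContrast(per_worm, float(deltas.mean()), sem, p, n)
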