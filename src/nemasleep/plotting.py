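"""Figure helpers following the house plotting conventions.

Box summaries show individual points, a 25-75% box, 10-90% whiskers, a thin
gray median line and a bold black mean line; trace panels overlay smoothed
velocity with detected sleep bouts.
"""

from __future__ import annotations

import numpy as np

from .scoring import BoutSet

__all__ = ["box_summary", "plot_track_with_bouts"]


def box_summary(groups: dict[str, np.ndarray], ax=None, jitter_seed: int = 0):
    """Boxplot of value groups in the package's house style."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(jitter_seed)
    for i, (label, vals) in enumerate(groups.items()):
        vals = np.asarray(vals, dtype=float)
        q10, q25, q50, q75, q90 = np.percentile(vals, [10, 25, 50, 75, 90])
        ax.add_patch(plt.Rectangle((i - 0.25, q25), 0.5, q75 - q25,
                                   fill=False, edgecolor="k"))
        ax.plot([i, i], [q10, q25], "k-", lw=0.8)
        ax.plot([i, i], [q75, q90], "k-", lw=0.8)
        ax.plot([i - 0.25, i + 0.25], [q50, q50], color="gray", lw=0.8)
        ax.plot([i - 0.25, i + 0.25], [vals.mean()] * 2, color="k", lw=2.0)
        ax.plot(i + rng.uniform(-0.15, 0.15, vals.size), vals, "o",
                ms=3, alpha=0.5)
    ax.set_xticks(range(len(groups)), list(groups))
    return ax


def plot_track_with_bouts(track, bouts: BoutSet, ax=None):
    """Smoothed velocity trace with detected sleep bouts shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    t = track["t_s"].to_numpy() / 60.0
    ax.plot(t, track["v_smooth"], "k-", lw=0.8, label="smoothed velocity")
    for s, e in bouts.bouts:
        ax.axvspan(s / 60.0, e / 60.0, color="tab:blue", alpha=0.25, lw=0)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("velocity (um/s)")
    return ax
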