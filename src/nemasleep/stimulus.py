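"""Post hoc classification and quantification of stimulation trials.

Optogenetic and light-stimulation trials are classified into "wake",
"sleep" or "excluded" from the worm's behavioral state before the stimulus,
then summarized per worm and compared across conditions.

Classification rules (per trial):

* responsiveness -- "sleep" if the worm was continuously in a sleep bout
  for the entire 3.5 min before stimulus onset, "wake" if it was never in a
  sleep bout in that window, "excluded" otherwise (episodes of both states).
* reversibility -- "sleep" if asleep for at least 95% of the 3.5 min before
  the stimulus; otherwise "wake" if asleep for less than 25% of the 15-min
  baseline; otherwise "excluded".  The sleep criterion takes precedence
  (both can hold at once; sleep is the stricter, rarer condition).

Response metrics: the acceleration of a trial is the ordinary-least-squares
slope of speed over the first minute of stimulation; window averages use
0-5 min after stimulus end (reversibility) or 2.5-7.5 min after light end
(homeostasis).  Trials are averaged within each worm before any test, and
percentages are reported rounded half-up to one decimal, matching the
bookkeeping convention of the source experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "StimulusTrial",
    "ClassificationTally",
    "classify_trial",
    "tally",
    "acceleration",
    "percent_change",
    "response_summary",
    "round_half_up_pct",
]

RESP_PRE_S = 210.0      # 3.5 min pre-stimulus classification window
REV_BASELINE_S = 900.0  # 15 min reversibility baseline
REV_POST_S = 300.0      # 5 min post-stimulus averaging window
HOMEO_POST_S = (150.0, 450.0)  # 2.5-7.5 min after light end


@dataclass(frozen=True)
class StimulusTrial:
    """One baseline/stimulus/post epoch of a single worm.

    ``sleep`` is the per-frame sleep-bout indicator derived from the same
    trial's behavior by :mod:`nemasleep.scoring`.  ``true_label`` is only
    set by the synthetic generator (ground truth for tests).
    """

    worm_id: str
    trial_id: int
    condition: str
    t: np.ndarray
    v: np.ndarray
    dff: np.ndarray
    sleep: np.ndarray
    stim_onset_s: float
    stim_end_s: float
    dt: float
    true_label: str | None = None

    def __post_init__(self) -> None:
        n = self.t.size
        if not (self.v.size == self.dff.size == self.sleep.size == n):
            raise ValueError("all traces must share one frame grid")
        if not (0 <= self.stim_onset_s < self.stim_end_s):
            raise ValueError("invalid stimulus epoch")


@dataclass(frozen=True)
class ClassificationTally:
    """Counts and one-decimal percentages of trial classifications."""

    n_total: int
    n_wake: int
    n_sleep: int
    n_excluded: int
    pct_wake: float
    pct_sleep: float
    pct_excluded: float

    def __post_init__(self) -> None:
        if self.n_wake + self.n_sleep + self.n_excluded != self.n_total:
            raise ValueError("counts must sum to n_total")


def round_half_up_pct(count: int, total: int) -> float:
    """``100*count/total`` rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tally(labels) -> ClassificationTally:
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to tally")
    bad = set(labels) - {"wake", "sleep", "excluded"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    n = len(labels)
    nw = labels.count("wake")
    ns = labels.count("sleep")
    ne = labels.count("excluded")
    return ClassificationTally(
        n_total=n, n_wake=nw, n_sleep=ns, n_excluded=ne,
        pct_wake=round_half_up_pct(nw, n),
        pct_sleep=round_half_up_pct(ns, n),
        pct_excluded=round_half_up_pct(ne, n),
    )


def _frac_asleep(trial: StimulusTrial, t_from: float, t_to: float) -> float:
    mask = (trial.t >= t_from) & (trial.t < t_to)
    if not mask.any():
        raise ValueError("empty classification window")
    return float(trial.sleep[mask].mean())


def classify_trial(trial: StimulusTrial, mode: str = "responsiveness") -> str:
    """Label a trial ``"wake"``, ``"sleep"`` or ``"excluded"`` (see module
    docstring for the rules).  A trial whose recording does not cover the
    required pre-window is excluded."""
    if mode == "responsiveness":
        if trial.stim_onset_s - RESP_PRE_S < trial.t[0] - 1e-9:
            return "excluded"
        frac = _frac_asleep(trial, trial.stim_onset_s - RESP_PRE_S,
                            trial.stim_onset_s)
        if frac == 1.0:
            return "sleep"
        if frac == 0.0:
            return "wake"
        return "excluded"
    if mode == "reversibility":
        if trial.stim_onset_s - REV_BASELINE_S < trial.t[0] - 1e-9:
            return "excluded"
        frac_pre = _frac_asleep(trial, trial.stim_onset_s - RESP_PRE_S,
                                trial.stim_onset_s)
        if frac_pre >= 0.95:
            return "sleep"
        frac_base = _frac_asleep(trial, trial.stim_onset_s - REV_BASELINE_S,
                                 trial.stim_onset_s)
        if frac_base < 0.25:
            return "wake"
        return "excluded"
    raise ValueError(f"unknown mode: {mode!r}")


def acceleration(trial: StimulusTrial, window_s: float = 60.0) -> float:
    """OLS slope (um/s^2) of speed over the first minute of stimulation."""
    mask = (trial.t >= trial.stim_onset_s) & \
           (trial.t < trial.stim_onset_s + window_s)
    t, v = trial.t[mask], trial.v[mask]
    if t.size < 2:
        raise ValueError("need >= 2 frames in the acceleration window")
    if np.ptp(t) == 0:
        raise ValueError("constant time vector")
    return float(np.polyfit(t, v, 1)[0])


def percent_change(trace, t, baseline_window: tuple[float, float],
                   response_window: tuple[float, float]) -> float:
    """100 * (mean(response) - mean(baseline)) / |mean(baseline)|."""
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    bmask = (t >= baseline_window[0]) & (t < baseline_window[1])
    rmask = (t >= response_window[0]) & (t < response_window[1])
    if not bmask.any() or not rmask.any():
        raise ValueError("empty baseline or response window")
    b = trace[bmask].mean()
    if b == 0:
        raise ValueError("zero baseline mean: percent change undefined")
    return float(100.0 * (trace[rmask].mean() - b) / abs(b))


@dataclass(frozen=True)
class ResponseSummary:
    """Per-condition (or per-state) effects and the group comparison."""

    per_worm: pd.DataFrame
    effects: dict
    test: stats.TestResult | None
    tallies: dict


def _post_window_mean(trial: StimulusTrial, lo: float, hi: float,
                      metric: str) -> float:
    trace = getattr(trial, metric)
    mask = (trial.t >= trial.stim_end_s + lo) & (trial.t < trial.stim_end_s + hi)
    if not mask.any():
        raise ValueError("trial does not cover the post-stimulus window")
    return float(trace[mask].mean())


def response_summary(trials: list[StimulusTrial], mode: str,
                     metric: str = "v") -> ResponseSummary:
    """Classify, average per worm, and compare.

    ``mode="responsiveness"``: per worm, mean stimulation-onset acceleration
    of its sleep trials and of its wake trials; paired Wilcoxon across worms
    that contributed both states.

    ``mode="reversibility"`` / ``mode="homeostasis"``: per worm, mean of
    ``metric`` over the mode's post-stimulus window across all its
    (non-excluded for reversibility) trials; two-sample t (Welch) between
    the two condition labels present (e.g. ATR+ vs ATR-).  Worms with no
    usable trials are dropped.
    """
    if not trials:
        raise ValueError("no trials supplied")
    if mode == "responsiveness":
        rows = []
        for tr in trials:
            label = classify_trial(tr, "responsiveness")
            rows.append((tr.worm_id, tr.condition, label,
                         acceleration(tr) if label != "excluded" else np.nan))
        df = pd.DataFrame(rows, columns=["worm_id", "condition", "label",
                                         "accel"])
        per_worm = (df[df.label.isin(["wake", "sleep"])]
                    .groupby(["worm_id", "label"])["accel"].mean()
                    .unstack())
        paired = per_worm.dropna(subset=["wake", "sleep"]) \
            if {"wake", "sleep"} <= set(per_worm.columns) else per_worm.iloc[:0]
        test = None
        if len(paired) >= 2:
            test = stats.wilcoxon_signed_rank(paired["sleep"], paired["wake"])
        effects = {
            s: stats.summarize(per_worm[s].dropna().to_numpy(),
                               per_worm[s].dropna().index.to_numpy())
            for s in per_worm.columns
        }
        tallies = {"all": tally(df["label"])}
        return ResponseSummary(per_worm.reset_index(), effects, test, tallies)

    if mode in ("reversibility", "homeostasis"):
        lo, hi = (0.0, REV_POST_S) if mode == "reversibility" else HOMEO_POST_S
        rows = []
        for tr in trials:
            label = (classify_trial(tr, "reversibility")
                     if mode == "reversibility" else "wake")
            if mode == "reversibility" and label == "excluded":
                rows.append((tr.worm_id, tr.condition, label, np.nan))
                continue
            rows.append((tr.worm_id, tr.condition, label,
                         _post_window_mean(tr, lo, hi, metric)))
        df = pd.DataFrame(rows, columns=["worm_id", "condition", "label",
                                         "value"])
        usable = df.dropna(subset=["value"])
        per_worm = (usable.groupby(["condition", "worm_id"])["value"]
                    .mean().reset_index())
        conditions = sorted(per_worm["condition"].unique())
        effects = {
            c: stats.summarize(
                per_worm.loc[per_worm.condition == c, "value"].to_numpy(),
                per_worm.loc[per_worm.condition == c, "worm_id"].to_numpy())
            for c in conditions
        }
        test = None
        if len(conditions) == 2:
            a = per_worm.loc[per_worm.condition == conditions[0], "value"]
            b = per_worm.loc[per_worm.condition == conditions[1], "value"]
            if len(a) >= 2 and len(b) >= 2:
                test = stats.two_sample_t(a, b)
        tallies = {c: tally(df.loc[df.condition == c, "label"])
                   for c in conditions} if mode == "reversibility" else {}
        return ResponseSummary(per_worm, effects, test, tallies)

    raise ValueError(f"unknown mode: {mode!r}")
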