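"""Synthetic worm recordings with known ground truth.

Every downstream stage of the pipeline (scoring, ROI quantification,
alignment, stimulus classification, survival statistics) is exercised
against data from this module, so each generator is a pure, seeded function
that also returns the ground truth it embedded.

The behavioral model is a two-state (wake/sleep) semi-Markov process: wake
episodes are exponentially distributed, sleep-bout durations are Gaussian
(clipped below at one frame), and the per-frame speed is the state mean plus
Gaussian noise truncated at zero.  RIS-like calcium activity rises
instantaneously at each bout onset and decays exponentially -- the simplest
trace shape consistent with onset-locked activation of a sleep-active
neuron.  Image stacks place a Gaussian nucleus at the simulated position
with peak brightness proportional to the ROI intensity trace, on a noisy
background.

Speed regimes per life stage put the wake mode at twice the stage's scoring
cutoff: empirically chosen cutoffs bisect the bimodal speed distribution,
so this is the regime in which such a cutoff is meaningful.  See
docs/methods.md for the full rationale and for what these simulations do
not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimSpec",
    "GroundTruth",
    "simulate_track",
    "simulate_stack",
    "simulate_survival",
    "simulate_stim_trials",
    "implied_sleep_survival_slope",
    "regime_spec",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated recording.

    Times are in seconds, speeds in um/s, intensities in arbitrary camera
    units, geometry in pixels.  ``dt`` is the frame interval (10 s at the
    0.1 fps long-term imaging rate; 0.5 s at the 2 fps stimulation rate).
    """

    duration: float = 10800.0          # 3 h, the standard scoring movie
    dt: float = 10.0
    wake_speed_mean: float = 6.0
    sleep_speed_mean: float = 0.0
    speed_noise_sd: float = 0.6
    bout_rate: float = 1.2             # bouts/hour of wake->sleep entries
    bout_duration_mean: float = 1200.0
    bout_duration_sd: float = 240.0
    calcium_baseline: float = 200.0
    calcium_amplitude: float = 1.2     # fractional rise at bout onset
    calcium_decay_tau: float = 100.0
    roi_noise_sd: float = 0.0          # additive noise on the ROI trace
    image_size: int = 64
    nucleus_sigma: float = 2.0
    background_noise_sd: float = 2.0
    px_to_um: float = 3.0   # 64 px -> ~190 um, an L1 microchamber
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if not (self.wake_speed_mean > self.sleep_speed_mean >= 0):
            raise ValueError("need wake_speed_mean > sleep_speed_mean >= 0")
        for name in ("speed_noise_sd", "bout_duration_sd", "roi_noise_sd",
                     "background_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bout_rate < 0:
            raise ValueError("bout_rate must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually embedded, on the emitted frame grid."""

    true_bouts: list[tuple[float, float]]
    true_sleep_fraction: float
    true_transient_amplitude: float
    per_worm_lifetime: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# stage presets: wake mode at 2x the scoring cutoff, noise at 10% of wake;
# chamber tracks are multi-day, the rest are 3-h movies
_REGIMES: dict[str, dict] = {
    "adult": dict(wake_speed_mean=1.0, speed_noise_sd=0.1,
                  bout_rate=0.9, bout_duration_mean=1200.0,
                  bout_duration_sd=240.0),
    "dauer": dict(wake_speed_mean=1.0, speed_noise_sd=0.1,
                  bout_rate=0.9, bout_duration_mean=1200.0,
                  bout_duration_sd=240.0),
    "arrested_l1": dict(wake_speed_mean=6.0, speed_noise_sd=0.6,
                        bout_rate=1.2, bout_duration_mean=1200.0,
                        bout_duration_sd=240.0),
    "fed_l1": dict(wake_speed_mean=2.4, speed_noise_sd=0.24,
                   bout_rate=1.2, bout_duration_mean=900.0,
                   bout_duration_sd=180.0),
    "chamber_survival": dict(wake_speed_mean=6.0, speed_noise_sd=0.6,
                             bout_rate=0.3, bout_duration_mean=3600.0,
                             bout_duration_sd=720.0,
                             duration=40.0 * 3600.0),
}


def regime_spec(stage: str, rng_seed: int = 0, **overrides) -> SimSpec:
    """A :class:`SimSpec` emulating the speed regime of a life-stage preset."""
    if stage not in _REGIMES:
        raise KeyError(f"unknown stage regime: {stage!r}; "
                       f"choose from {sorted(_REGIMES)}")
    kw = dict(_REGIMES[stage])
    kw.update(overrides)
    return SimSpec(rng_seed=rng_seed, **kw)


def _draw_bouts(spec: SimSpec, rng: np.random.Generator):
    """Alternating wake/sleep episode boundaries over [0, duration]."""
    if spec.bout_rate == 0:
        return []
    wake_mean = 3600.0 / spec.bout_rate
    bouts = []
    t = rng.exponential(wake_mean)
    while t < spec.duration:
        dur = rng.normal(spec.bout_duration_mean, spec.bout_duration_sd)
        dur = max(dur, spec.dt)
        end = min(t + dur, spec.duration)
        bouts.append((t, end))
        t = end + rng.exponential(wake_mean)
    return bouts


def simulate_track(spec: SimSpec, bouts: list[tuple[float, float]] | None = None
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one worm's track table and its ground truth.

    Returns a track table (columns ``frame, t_s, x_um, y_um, roi_intensity``)
    and a :class:`GroundTruth` whose bouts are quantized to the frame grid,
    so the sleep fraction equals the fraction of frames in the sleep state
    exactly.  ``bouts`` may be supplied to program the episode structure
    explicitly (e.g. a single noiseless bout for a limit test); otherwise it
    is drawn from the semi-Markov model.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = int(round(spec.duration / spec.dt))
    if n < 2:
        raise ValueError("duration must cover at least 2 frames")
    t = np.arange(n) * spec.dt

    drawn = _draw_bouts(spec, rng) if bouts is None else sorted(bouts)
    asleep = np.zeros(n, dtype=bool)
    for s, e in drawn:
        asleep[(t >= s) & (t < e)] = True
    # the first frame has no displacement measurement (velocity copies
    # frame 1), so its state follows frame 1 to keep truth and scoring
    # on the same footing
    asleep[0] = asleep[1]

    # ground-truth bouts on the frame grid
    true_bouts: list[tuple[float, float]] = []
    i = 0
    while i < n:
        if asleep[i]:
            j = i
            while j + 1 < n and asleep[j + 1]:
                j += 1
            true_bouts.append((i * spec.dt, (j + 1) * spec.dt))
            i = j + 1
        else:
            i += 1

    mean_speed = np.where(asleep, spec.sleep_speed_mean, spec.wake_speed_mean)
    v = np.clip(mean_speed + rng.normal(0.0, spec.speed_noise_sd, n), 0.0, None)

    # random-walk positions with persistent heading, reflected at the walls
    extent = spec.image_size * spec.px_to_um
    margin = max(4.0 * spec.nucleus_sigma, 6.0) * spec.px_to_um
    lo, hi = margin, extent - margin
    if lo >= hi:
        raise ValueError("image_size too small for the nucleus margin")
    turn_sd = 0.6
    headings = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(
        rng.normal(0.0, turn_sd, n))
    steps = v * spec.dt
    dxs = steps * np.cos(headings)
    dys = steps * np.sin(headings)
    x = np.empty(n)
    y = np.empty(n)
    x[0] = y[0] = 0.5 * extent
    for i in range(1, n):
        # reflect at the chamber walls; flipping a component preserves the
        # step length, so the emitted velocity stays consistent
        dx, dy = dxs[i], dys[i]
        xi, yi = x[i - 1] + dx, y[i - 1] + dy
        if not lo <= xi <= hi:
            xi = x[i - 1] - dx
        if not lo <= yi <= hi:
            yi = y[i - 1] - dy
        x[i] = min(max(xi, lo), hi)
        y[i] = min(max(yi, lo), hi)

    # onset-locked calcium transients with exponential decay
    f = np.full(n, 1.0)
    for s, _ in true_bouts:
        mask = t >= s
        f[mask] += spec.calcium_amplitude * np.exp(-(t[mask] - s)
                                                   / spec.calcium_decay_tau)
    roi = spec.calcium_baseline * f
    if spec.roi_noise_sd > 0:
        roi = np.clip(roi + rng.normal(0.0, spec.roi_noise_sd, n), 1e-6, None)

    track = pd.DataFrame({
        "frame": np.arange(n),
        "t_s": t,
        "x_um": x,
        "y_um": y,
        "roi_intensity": roi,
    })
    truth = GroundTruth(
        true_bouts=true_bouts,
        true_sleep_fraction=float(asleep.mean()),
        true_transient_amplitude=spec.calcium_amplitude,
    )
    return track, truth


def simulate_stack(track: pd.DataFrame, spec: SimSpec) -> np.ndarray:
    """Render a track into a (frames, H, W) image stack.

    Each frame holds a Gaussian spot of width ``nucleus_sigma`` centered at
    the track position with peak equal to the frame's ROI intensity, plus
    clipped Gaussian background noise.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    size = spec.image_size
    n = len(track)
    rows = track["y_um"].to_numpy() / spec.px_to_um
    cols = track["x_um"].to_numpy() / spec.px_to_um
    if np.any((rows < 0) | (rows >= size) | (cols < 0) | (cols >= size)):
        raise ValueError("track positions fall outside the image bounds")
    peaks = track["roi_intensity"].to_numpy()
    frames = np.clip(rng.normal(0.0, spec.background_noise_sd,
                                (n, size, size)), 0.0, None)
    reach = int(np.ceil(4 * spec.nucleus_sigma))
    for i in range(n):
        r0, c0 = rows[i], cols[i]
        ra = max(0, int(r0) - reach)
        rb = min(size, int(r0) + reach + 1)
        ca = max(0, int(c0) - reach)
        cb = min(size, int(c0) + reach + 1)
        rr, cc = np.meshgrid(np.arange(ra, rb), np.arange(ca, cb),
                             indexing="ij")
        spot = peaks[i] * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                 / (2.0 * spec.nucleus_sigma ** 2))
        frames[i, ra:rb, ca:cb] += spot
    return frames.astype(np.float32)


def simulate_survival(n_worms: int, base_hazard: float, sleep_effect: float,
                      sleep_fractions, seed: int = 0) -> pd.DataFrame:
    """Per-worm lifetimes under a sleep-modulated exponential hazard.

    Worm ``i`` dies at rate ``base_hazard * sleep_effect ** (-s_i)`` per day,
    where ``s_i`` is its sleep fraction: ``sleep_effect > 1`` makes sleep
    protective, ``sleep_effect = 1`` makes lifetime independent of sleep.
    Returns a lifetime-form survival table (``worm_id, sleep_fraction,
    lifetime_days, censored``).
    """
    s = np.asarray(sleep_fractions, dtype=float)
    if n_worms <= 0 or s.size != n_worms:
        raise ValueError("need one sleep fraction per worm, n_worms > 0")
    if base_hazard <= 0 or sleep_effect <= 0:
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)
    hazard = base_hazard * sleep_effect ** (-s)
    lifetimes = rng.exponential(1.0 / hazard)
    return pd.DataFrame({
        "worm_id": [f"w{i:04d}" for i in range(n_worms)],
        "sleep_fraction": s,
        "lifetime_days": lifetimes,
        "censored": np.zeros(n_worms, dtype=bool),
    })


def implied_sleep_survival_slope(base_hazard: float, sleep_effect: float,
                                 sleep_fractions) -> float:
    """Population slope implied by the hazard model *under the mean +/- SD
    exclusion rule* of the sleep-survival fit.

    The fit first discards worms whose lifetime falls outside
    ``[mean - SD, mean + SD]`` of the lifetime marginal, which truncates the
    exponential tails and attenuates the raw slope.  This closed form
    propagates the truncation: with per-worm rate ``lam_i``, population
    moments of the exponential mixture give the truncation bounds ``[a, b]``,
    and the included-worm conditional means ``E[T | a <= T <= b, lam_i]``
    are regressed on sleep fraction, weighted by the inclusion probability.
    """
    s = np.asarray(sleep_fractions, dtype=float)
    lam = base_hazard * sleep_effect ** (-s)
    mean = np.mean(1.0 / lam)
    var = np.mean(2.0 / lam ** 2) - mean ** 2
    a, b = max(mean - np.sqrt(var), 0.0), mean + np.sqrt(var)
    ea, eb = np.exp(-lam * a), np.exp(-lam * b)
    w = ea - eb                                   # P(a <= T <= b)
    # E[T; a<=T<=b] = (a + 1/lam) e^{-lam a} - (b + 1/lam) e^{-lam b}
    num = (a + 1.0 / lam) * ea - (b + 1.0 / lam) * eb
    m = num / w
    sbar = np.sum(w * s) / np.sum(w)
    return float(np.sum(w * (s - sbar) * m) / np.sum(w * (s - sbar) ** 2))


def simulate_stim_trials(n_worms: int, trials_per_worm: int,
                         mode: str = "responsiveness",
                         p_sleep: float = 0.3,
                         wake_accel: float = 0.02,
                         sleep_accel: float = 0.005,
                         condition: str = "ATR+",
                         post_effect: float = 0.0,
                         dt: float = 0.5,
                         seed: int = 0) -> list["StimulusTrial"]:
    """Simulated optogenetic/light-stimulation trials with known labels.

    ``mode="responsiveness"`` builds 2 fps blue-light trials (3.5 min
    pre-stimulus history, 3 min stimulus, 1 min post).  Each trial's
    pre-window is fully asleep with probability ``p_sleep``, a sleep/wake
    mixture (hence unclassifiable) with probability 0.1, and fully awake
    otherwise; the speed ramps with slope ``wake_accel`` or ``sleep_accel``
    (um/s^2) during the first stimulation minute.

    ``mode="reversibility"`` builds 30-min trials stimulated at 15 min for
    1.5 s; ``post_effect`` is added to the post-stimulus speed of every
    trial (the handle used to embed a condition contrast).
    """
    from .stimulus import StimulusTrial  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    trials: list[StimulusTrial] = []
    for w in range(n_worms):
        for k in range(trials_per_worm):
            if mode == "responsiveness":
                pre_s, stim_s, post_s = 210.0, 180.0, 60.0
                n_pre = int(pre_s / dt)
                n_stim = int(stim_s / dt)
                n_post = int(post_s / dt)
                n = n_pre + n_stim + n_post
                t = np.arange(n) * dt
                u = rng.uniform()
                if u < p_sleep:
                    label, sleep_pre = "sleep", np.ones(n_pre, bool)
                elif u < p_sleep + 0.1:
                    label = "excluded"
                    sleep_pre = rng.uniform(size=n_pre) < 0.5
                else:
                    label, sleep_pre = "wake", np.zeros(n_pre, bool)
                sleep = np.concatenate([sleep_pre, np.zeros(n_stim + n_post,
                                                            bool)])
                base = 0.2 if label == "sleep" else 2.0
                accel = sleep_accel if label == "sleep" else wake_accel
                v = base + rng.normal(0.0, 0.1, n)
                stim_t = t - pre_s
                ramp = (stim_t >= 0) & (stim_t < 60.0)
                v[ramp] += accel * stim_t[ramp]
                v[stim_t >= 60.0] += accel * 60.0
                v = np.clip(v, 0.0, None)
                trials.append(StimulusTrial(
                    worm_id=f"w{w:03d}", trial_id=k, condition=condition,
                    t=t, v=v, dff=np.zeros(n), sleep=sleep,
                    stim_onset_s=pre_s, stim_end_s=pre_s + stim_s, dt=dt,
                    true_label=label))
            elif mode == "reversibility":
                total, onset, stim_len = 1800.0, 900.0, 1.5
                n = int(total / dt)
                t = np.arange(n) * dt
                asleep_trial = rng.uniform() < p_sleep
                sleep = np.zeros(n, bool)
                if asleep_trial:
                    sleep[t < onset] = True
                    label = "sleep"
                else:
                    label = "wake"
                v = np.where(sleep, 0.2, 2.0) + rng.normal(0.0, 0.1, n)
                post = t >= onset + stim_len
                v[post] += post_effect
                v = np.clip(v, 0.0, None)
                trials.append(StimulusTrial(
                    worm_id=f"w{w:03d}", trial_id=k, condition=condition,
                    t=t, v=v, dff=np.zeros(n), sleep=sleep,
                    stim_onset_s=onset, stim_end_s=onset + stim_len, dt=dt,
                    true_label=label))
            else:
                raise ValueError(f"unknown mode: {mode!r}")
    return trials


def write_track_csv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, index=False)
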