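# Methods

This note documents the models and procedures `nemasleep` implements, the
parameters that matter, the design choices made where the underlying
conventions were genuinely open, and what the synthetic-data tests do and
do not demonstrate about real recordings.

## Behavioral scoring

**Velocity.** Per-frame speed is Euclidean displacement divided by the
elapsed time between frames (so dropped frames average over the true
interval); `v[0]` copies `v[1]` so bout detection receives a full-length
trace.  Positions may come from the tracked nucleus or from a whole-body
centroid; both are plain (x, y) columns of the track table.

**Smoothing.** The scoring smoother is first-degree local polynomial
regression (lowess) with tricube weights over a fixed number of points
(25 by default; at the 0.1 frame/s long-term rate that is a ~4-min
window).  The weight function and boundary rule of the original routine
are not specified anywhere, so this package fixes them: tricube weights
with distances normalized by `half + 1` (every point in the window keeps
positive weight), no robustness iterations, and windows truncated
*symmetrically* at the trace boundaries.  With a symmetric window and
symmetric weights the degree-1 fit at the center point reduces to a
normalized kernel average, but it remains the exact weighted-least-squares
solution and reproduces globally linear traces everywhere — the property
the tests pin to 1e-10 against a per-point `lstsq` oracle.  Even window
lengths are reduced by one (the 40-point survival-chamber preset smooths
over 39 points); the centered moving average used for display (5 points)
and chamber scoring follows the same conventions.

**Bout detection.** A sleep bout is a maximal run of frames with smoothed
velocity *strictly below* the cutoff (a frame exactly at the cutoff is
wake — the literal reading, fixed here for reproducibility) lasting at
least the stage minimum.  No gap merging: two sub-threshold runs separated
by a single supra-threshold frame are separate candidates.  Bout
boundaries sit at the first sub-threshold frame and one past the last, so
a run of `k` frames has duration `k·dt`.  Fraction-of-mean cutoffs
(survival chambers: 40% of mean velocity; frame subtraction: 20% of mean
activity) resolve against the mean of the trace being scored.  The
minimum bout for frame-subtraction scoring is not specified by its source;
the package defaults to 120 s and exposes it.

**Presets.** adult/dauer: 25-pt lowess, 0.5 µm/s, 180 s.  arrested L1:
25-pt, 3 µm/s, 180 s.  fed L1: 25-pt, 1.2 µm/s, 120 s.  chamber survival:
40-pt running average, 40% of mean v, 120 s.  Lethargus windows are an
input annotation (defined experimentally by the non-pumping period), never
computed.

## ROI quantification

**Localization.** The original nucleus-finding routine is undocumented, so
the package uses the minimal robust scheme: Gaussian-blur each frame
(σ = 2 px), take the argmax within a 31-px box around the previous
position (full frame on the first frame), and fall back to a full-frame
search when the in-box maximum collapses below half the previously
tracked peak — at 0.1 frame/s a crawling worm routinely jumps farther
than any reasonable tracking box, and without re-acquisition the ROI
reads background during wake.  Frames without contrast are flagged, not
interpolated.

**Top-k ROI.** The readout is the mean of the k brightest pixels in a
square around the nucleus (30 of 11×11 for RIS, 500 of 69×69
pan-neuronal).  Squares are clipped at image edges (worms touch chamber
walls); it is an error only if fewer than k pixels remain.  The statistic
is monotone in every pixel value and linear in overall intensity scaling.

**ΔF/F baseline.** `dff = (F − F0)/F0`.  No definition of `F0` survives
in the source material, and printed summary percentages cannot pin it
down without the raw data, so the package makes the choice explicit:
`trace_mean` (default; gives mean-zero ΔF/F, convenient for contrasts) or
`percentile` (default 8th; approximates the transient-free resting
intensity and should be used when absolute amplitudes matter — the
round-trip tests use it).  The choice is recorded in the run log.  Note
the percentile baseline has a small downward bias under measurement noise
(the 8th percentile of a noisy constant sits ~1.4 SD below it), which
inflates ΔF/F by roughly `1.4·σ/F0`; the alignment tests account for this
when checking baseline flatness.

**Frame subtraction.** Activity between consecutive frames is the count
of pixels whose absolute change exceeds a noise threshold, default 3× the
median absolute frame-to-frame change of the stack.  The original
"intensity counts" statistic is ambiguous (summed |Δ| vs changed-pixel
count); the count interpretation is implemented, with the threshold
configurable.

## Bout-onset alignment

Traces are aligned on a common grid from 15 min before to 30 min after
each bout onset.  Onsets with any other bout intruding into the 15-min
pre-window are excluded (flat-baseline rule); onsets whose window is not
fully covered are dropped and counted separately, so
`rows + excluded + partial = total onsets`.  The onset contrast averages
ΔF/F over [−5 min, 0) and [0, +5 min] per worm first — n is worms, the
reporting convention of these experiments — and compares the pairs with
the Wilcoxon signed-rank test.  The 5-point display smoothing is applied
only to exported traces, never before statistics.

## Stimulation trials

Responsiveness: a trial is "sleep" if the worm was in a sleep bout for
100% of the 3.5 min before stimulus onset, "wake" at 0%, otherwise
excluded.  (The source states the wake rule in two conflicting forms —
"3.5 min before stimulation" vs "throughout the baseline"; the 3.5-min
reading is implemented.)  The 3.5-min window predates the 1-min imaging
baseline, so trial records must include pre-stimulus history; trials that
do not cover it are excluded with a reason.  Responsiveness is quantified
as the OLS slope of speed over the first minute of stimulation,
averaged per worm and compared sleep-vs-wake with the paired test.

Reversibility: "sleep" if asleep ≥ 95% of the final 3.5 min, else "wake"
if asleep < 25% of the 15-min baseline, else excluded.  Both criteria can
hold simultaneously; the sleep criterion is tested first (it is the
stricter, rarer condition).  Post-stimulus averages use 0–5 min after
stimulus end; the homeostasis window is 2.5–7.5 min after light end;
condition contrasts (e.g. ATR+ vs ATR−) use Welch's t test on per-worm
means.

Tally percentages are rounded half-up to one decimal, the convention the
published counts follow.  Recomputing all 24 printed percentages from
their counts reproduces every one except a single entry (123 of 273
printed as 40.1%, which recomputes to 45.1%); the audit reports it as a
discrepancy rather than matching it.

## Survival analysis

Cohort curves are `n_alive/n_total` per sampling day with binomial SE.
Half-times ("50% alive", "50% recovering") linearly interpolate between
the sampling days bracketing the first downward crossing of 0.5 — the
published half-times fall between sampling days, implying interpolation,
but the rule itself is unstated; linear is this package's choice.  Curves
that never reach 0.5 (or start below it) return `None`.

Per-day comparisons are 2×2 Fisher exact tests, Benjamini-Hochberg
corrected at 5% FDR within the comparison; BH here is deliberately
conservative plumbing (the source applies BH only to its multi-genotype
comparisons) and can be switched off (`q=None`).  Whole-curve comparisons
use the standard two-group log-rank test (via lifelines), honoring
censoring.

The sleep-survival fit regresses per-worm lifetime on per-worm sleep
fraction by OLS after a *single-pass* exclusion of worms with lifetime
outside mean ± SD of the lifetime marginal (computed once, before
fitting, not iterated).  Per-worm sleep fractions for chamber-housed
worms use the chamber preset over day 2–4 of starvation and require at
least 35 h of coverage; under-covered worms are flagged and excluded from
fits.  Worm volume for consumption normalization is the elongated
cylinder `π r² L`.

## The synthetic-data model

Behavior is a two-state semi-Markov process: exponential wake episodes
(rate = `bout_rate`), Gaussian bout durations (clipped at one frame), and
per-frame speed = state mean + Gaussian noise truncated at zero.  The
first frame's state copies frame 1 (its velocity is not measurable).
Ground truth is quantized to the frame grid, so the embedded sleep
fraction is exactly the fraction of sleep frames.  Positions follow a
persistent-heading random walk with wall reflection inside a chamber
sized like a real L1 microchamber (64 px × 3 µm/px ≈ 190 µm); reflection
flips a step component, preserving step length so the emitted speed stays
consistent with the displacement a tracker would measure.

Speed regimes per stage place the wake mode at **twice the stage's
scoring cutoff** (adult 1.0, arrested L1 6.0, fed L1 2.4 µm/s), with
noise SD at 10% of the wake mode.  Rationale: the cutoffs were chosen
empirically to separate quiescent from active episodes, i.e. they bisect
the bimodal speed distribution; a generator violating that relation would
describe an experiment in which the published cutoffs were the wrong
ones.  Default bout statistics: ~20-min bouts (SD 4 min) at ~1/h for the
3-h movie regimes, ~1-h bouts for the multi-day chamber regime, giving
sleep fractions in the 0.3–0.45 range typical of arrested larvae.

Calcium: `F = F_base · (1 + A · exp(−Δt/τ))` summed over bout onsets,
with `A = 1.2` (ΔF/F transients of order unity, as observed for RIS) and
`τ = 100 s`; instantaneous rise is a deliberate simplification of the
onset-locked activation, not a kinetic claim.  Image stacks place a
Gaussian spot (σ = 2 px) with peak equal to the ROI trace on clipped
Gaussian background noise.

Survival: per-worm lifetimes are exponential with hazard
`base_hazard · sleep_effect^(−s)`.  With `sleep_effect = 1` lifetime is
independent of sleep; the protective scenario uses `sleep_effect = 10`
(a fully sleeping worm lives 10× longer; over the simulated sleep range
0–0.6 that is a ~4× lifetime spread, in line with the strength of the
observed sleep-survival correlation).  Because the fit excludes lifetimes
outside mean ± SD, the slope it estimates is attenuated relative to the
raw regression of conditional means; the generator therefore provides a
closed-form *implied slope* that propagates the truncation (truncated-
exponential conditional means, weighted by inclusion probability), and
recovery is judged against that value on the scale of the regression's
own slope SE.

**What passing these simulations shows — and does not.**  The generator
emulates the statistical structure the pipeline's rules key on: bimodal
speeds, long quiescence bouts, onset-locked transients, Poisson-like bout
entries, exponential survival.  It does not model posture, pumping,
photobleaching, focus drift, body-wall fluorescence, tracking occlusions,
or non-exponential aging hazards.  Round-trip fidelity on these
simulations therefore validates the *computations* (thresholds, windows,
exclusions, estimators), not the biological adequacy of the presets for
any particular new recording setup.

## Numerical conventions and edge cases

* Two-sided p-values throughout.  Wilcoxon drops zero differences; an
  all-zero difference vector returns p = 1 by convention.  Exact null
  distributions: Wilcoxon up to 25 nonzero untied pairs; Mann-Whitney for
  `n1·n2 ≤ 400` without ties, full permutation enumeration for small tied
  samples; normal approximations with continuity/tie correction above.
  Two-sided exact p's follow the "double the smaller tail" convention
  (with ties the permutation distribution of U is not symmetric, so this
  is not equivalent to tail reflection).  Welch's t is the default
  two-sample t; two constant equal groups give p = 1.
* Benjamini-Hochberg follows the standard step-up rule with monotone
  adjusted p-values, via statsmodels.
* Fisher's exact test is conservative by construction (attained type-I
  error ≈ 0.03 at n = 100/group, lower for smaller n); the test-suite
  property checks hold the continuous-data tests to the nominal 5% level
  and Fisher to validity (never anticonservative).
* Group summaries average within worm first, then across worms
  (SEM = SD/√n_worms, ddof = 1); SEM is undefined (NaN) for one worm.
* Noiseless scoring round-trips are checked on the unsmoothed velocity:
  smoothing exists to suppress noise, and on a noiseless step trace any
  finite window only distorts edges (the 40-pt running average erodes
  ~8 frames per edge even without noise).  Ground-truth comparisons drop
  truth bouts shorter than the preset minimum (e.g. one truncated by the
  end of the recording), which the scorer by definition cannot report.
* Problem sizes in the test suite and acceptance script (100 worms per
  preset for scoring round-trips, 6–8 rendered worms for imaging
  round-trips, 8 replicate survival fits of 200 worms, 2000-replicate
  null calibrations) were chosen to make the checks statistically
  meaningful while keeping a full run in the tens of seconds.

## Known limitations

* The tracker is a single-blob follower; it will fail on multi-worm
  fields (real L1 chambers can hold up to four worms per field) and on
  strongly bleaching recordings.
* `StageParams` cutoffs are those shipped; nothing recalibrates them to a
  new microscope's noise floor.
* The survival module offers no parametric hazard models or frailty
  terms, and the sleep-survival fit is strictly the published
  mean ± SD-then-OLS recipe.
* CSV/TIFF are the only I/O formats; proprietary microscope formats are
  out of scope.
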