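# Methods

`speechgaze` reimplements, as a tested pipeline, an eye-tracking analysis
of how young deaf and hearing children watch a silently speaking face:
raw 250 Hz gaze samples are classified against moving facial areas of
interest (AOIs), condensed into percentage Net Dwell Time (%NDT) per
speech segment, scored for the eyes–mouth–eyes "social-tuning" viewing
pattern, and related to speechreading and reading outcomes. Because no
raw data from such studies are available, a synthetic cohort generator
with full ground truth is a first-class component: every downstream claim
the package makes is validated by parameter recovery against that ground
truth.

## AOI geometry

The talker's face carries two equal semicircular AOIs forming a disk
centred on the midpoint of the eyes-centre and mouth-centre landmarks.
The dividing diameter is perpendicular to the eyes–mouth axis (not
horizontal on screen), so the flat edges meet "on the nose" and remain
equidistant from the two landmarks as the head moves; landmark keyframes
are linearly interpolated over time and clamped outside the tracked
range. The disk radius is `radius_factor × half the eyes–mouth distance`
with default `radius_factor = 2.0`: the radius then equals the full
inter-landmark distance, generously covering the eye and mouth regions
while keeping the two half-disks disjoint. A gaze point outside the disk
is `NEITHER`; inside, the sign of its projection on the mouth-to-eyes
axis decides, and a projection of exactly zero (within 1e-9) is labelled
`MOUTH` — any fixed tie-break is acceptable on this measure-zero set, and
a deterministic one keeps runs reproducible.

## Dwell-time extraction

%NDT is sample-based, not fixation-based: each sample is credited with
the time to the next sample (the nominal 4 ms period for the last, so
dropped frames are absorbed by the preceding sample), clipped to the
segment window, and classified against the AOI pair evaluated at the
sample's own timestamp. Three half-open windows partition each trial:
pre-speech `[0, onset)`, speech `[onset, offset)`, post-speech
`[offset, duration)`, where onset/offset are the hand-coded visual-speech
events. The %NDT denominator is the **full segment length**, not valid
tracking time: tracking loss lowers %NDT rather than renormalising it,
which is consistent with the quality-control rule that makes low-tracking
trials ineligible instead of reweighted. Percentages are averaged
unweighted across a participant's retained trials (videos of different
lengths are comparable on the percentage scale); a segment of zero length
yields missing cells, which drop out of the average rather than counting
as zero.

Drift corrections — positional offsets estimated on the fixation screens
between trials — apply cumulatively from the named trial to all later
trials of that participant. Only one (right-eye) stream is modelled.

## Quality control

A trial survives only if the child was looking at the screen — a valid
sample whose position lies inside the screen rectangle — for **strictly
more** than 50% of the speech window; exactly 50% is removed, which
satisfies both the "less than 50% removed" and the "more than 50%
retained" phrasings of the rule. Off-task trials cannot be recomputed
from gaze data and are an explicit input list (default empty).
Participants with fewer than eight retained trials (of twelve) are
excluded.

## Social-tuning ratio

The social-tuning ratio condenses the eyes-before-speech,
mouth-during-speech, eyes-after-speech pattern into one number. The
published rendering of the score exists only as an image in the source
article, so this package uses a declared operationalisation: the
pattern-concordant share of total eyes+mouth dwell mass,

```
STR = (E_pre + M_speech + E_post)
      / (E_pre + M_pre + E_speech + M_speech + E_post + M_post)
```

computed on the participant's trial-averaged %NDT cells (a ratio of
averages, not an average of per-trial ratios). It is bounded in [0, 1],
invariant to uniform rescaling of the six cells, equals 0.5 when dwell is
indifferent to the pattern, and strictly increases whenever mass moves
from a discordant cell to its concordant partner. Every output row
carries `formula_version = "pattern-mass-v1"` so results computed under a
different operationalisation remain distinguishable. Cells of missing
segments are excluded from numerator and denominator alike; a participant
with no eyes/mouth dwell at all has no defined ratio and raises.

## Statistical layer

Two-sample contrasts use the pooled-variance t test by default, switching
to the Welch test when a two-sided F screen on the variance ratio rejects
equality at α = .05; the variant used is always reported. Cohen's d uses
the pooled SD in both variants so effect sizes stay comparable.
Correlations are Pearson with classical p-values and seeded percentile
bootstrap CIs (default 1000 replicates). Moderated regressions are OLS of
`y ~ x + g + x:g` (dummy `g` with its 0/1 level map recorded, optional
covariates); when the interaction's p-value is at or above
`alpha_reduce = .05` the model is refit without it and the reduced fit is
flagged as the reported one — both fits are always returned. The
composite reading score sums per-measure z-scores computed over the
combined analysed sample. p-values come from classical reference
distributions with bootstrap CIs alongside, since resampling inference is
used in this literature without a stated method.

## Synthetic cohorts

Each simulated trial follows one latent behaviour: the full social
pattern (probability `p_social`; gaze shifts lag speech onset/offset by
truncated-normal latencies), or one of three non-pattern behaviours —
mouth-only, eyes-only, or roaming (uniform 200–600 ms fixations over the
screen). **The non-pattern mixture is deliberately mouth-heavy by
default.** This was a forced design choice: the emulated population has
group mean social-tuning ratios of ~.37 (deaf) and ~.48 (hearing), both
*below* the 0.5 indifference point, alongside mouth %NDT of ~64–70
during speech. A symmetric non-pattern mixture contributes exactly 0.5 to
the expected ratio, and no setting of `p_social` and latencies can then
push the group mean below 0.5 while keeping mouth %NDT high — the
discordant mass (mouth dwell before and after speech) must dominate, so
the mixture weights are per-participant parameters with mouth-heavy
defaults.

Fixation jitter is isotropic Gaussian (default 18 px against an AOI
radius of 160 px); tracking loss arrives as runs of invalid samples
(per-sample start rate, geometric run lengths — deaf cells lose more,
emulating harder-to-track participants); occasional half-second
off-screen excursions leave samples valid but off-screen. Outcome scores
are linear in the participant's realized mouth %NDT and social-tuning
ratio with a deaf-specific STR slope, Gaussian noise, then rounding and
clipping to the 0–62 speechreading score range; the clipped fraction is
reported so recovery studies can verify censoring is negligible. Outcomes
are driven by metrics realized over *all* simulated trials — the child's
latent behaviour drives the score, while the analysis pipeline sees only
what survives its own QC.

Between-participant heterogeneity: `p_social` and the mouth share of the
non-pattern mass are Beta-distributed within each group × intervention
cell (concentration κ = 5–6), and the latency mean varies normally
between participants. The default cell parameters were calibrated once,
against full-pipeline group means at n = 200, to the emulated group
structure (deaf mouth %NDT ≈ 64.3, hearing ≈ 70.3, STR ≈ .37 / .48) and
then frozen; the stimulus set is a fixed table of twelve videos of
2.5–5 s with 400–800 ms pre-speech onsets and 500–700 ms post-speech
tails (trial durations in this corpus vary but are not otherwise
constrained, so these defaults are configurable, not claimed).

Two resolutions are available. `resolution="samples"` writes full 250 Hz
gaze streams and realizes metrics through the actual AOI pipeline;
`resolution="metrics"` draws the same latent behaviours and latencies but
computes each trial's dwell cells analytically (with jitter-fidelity,
validity and excursion factors applied in expectation), which makes
200-replicate studies at 1000 participants take seconds. The two agree in
group means to within ~2 percentage points of mouth %NDT and ~.005 of
STR. Large parameter-recovery runs (200 replicates, n = 500 per group)
use the metric resolution; all pipeline-behaviour tests use the sample
resolution.

`expected_metrics` provides the closed-form expected dwell profile for a
strategy (capped-latency expectations integrated numerically over the
truncated-normal survival function; a first-order Gaussian-crossing
approximation for jitter leakage, valid while jitter ≪ AOI radius). It is
the analytic oracle for convergence tests.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: segment-
locked gaze strategies of varying fidelity, realistic tracking loss and
off-screen excursions, trial-to-trial behavioural variability, and
outcomes linearly tied to gaze metrics with a group-dependent slope. It
does **not** emulate saccade dynamics or fixation microstructure, pupil
artefacts, smooth pursuit of the moving face, systematic calibration
drift within trials (drift corrections are exercised with explicit
offset files instead), or any nonlinearity in the outcome link. Passing
tests therefore demonstrate that the pipeline measures what it claims on
data with known truth — not that the behavioural model is a complete
account of children's gaze.

## Numerical choices and degenerate inputs

* Dividing-line tie-break → MOUTH; disk boundary counts as inside.
* Coincident landmarks raise a degenerate-geometry error; empty landmark
  tracks raise a missing-track error.
* Gaze timestamps must be strictly increasing within a trial; duplicated
  timestamps are an ordering error, not silently merged.
* The last sample of a stream is credited the nominal 4 ms period.
* An empty speech window makes the on-screen fraction undefined (error),
  and empty segments yield missing (NaN) %NDT cells, never zeros.
* Bootstrap resamples that are degenerate (zero variance, rank-deficient)
  are dropped from the percentile computation.
* Welch df falls back to the pooled value when both standard errors are
  zero; with one group's variance → 0 it approaches n−1 of the varying
  group.

## Problem sizes used in the validation suite

Dwell-oracle cross-check: 120 random trials against a 1 ms rasterization
oracle at 0.5 percentage-point tolerance. Parameter recovery: 200
replicates at n = 500 per hearing-status group (metric resolution),
requiring the mean estimates of the STR slope and its deaf interaction
within 2 Monte-Carlo SEs of truth. Interaction-reduction false retention:
600 replicates under a zero-interaction generator (600 rather than 200 so
the Monte-Carlo SE of the rate, ~0.9%, is small against the ±2% band).
Calibration: one full-pipeline cohort of 200. These sizes were chosen so
the whole validation runs in well under a minute of simulation time while
keeping Monte-Carlo error comfortably inside each tolerance.

## Known limitations

* The social-tuning formula is a declared stand-in for an unavailable
  published rendering; all outputs are tagged with the formula version.
* Whether the published score was a ratio of trial-averaged %NDT (as
  here) or an average of per-trial ratios is unknowable from the source;
  the former is better behaved when single trials have little AOI dwell.
* "Looking at the screen" is interpreted strictly (valid AND on-screen);
  a tracker that reports valid samples for off-screen gaze would be
  treated more conservatively here than by a validity-only rule.
* AOI dwell is credited whether or not the AOI disk lies wholly on
  screen; with the default face placement it always does.
* Sample-based %NDT slightly over-credits the pre-shift AOI around
  segment boundaries (a boundary-straddling sample keeps one label);
  at 250 Hz this is at most one 4 ms sample per transition.
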