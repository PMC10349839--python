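# Methods

This note documents the models, numerical choices and known limitations of
`gazefield`.  It covers, in order: display geometry and masking, session
design, oculomotor event detection, ROI analysis, the behavioral
(signal-detection) pipeline, the inferential statistics, and the synthetic
observer that generates all test data.

## Display geometry and masking

The display model is a flat screen at a fixed viewing distance `D` (default
82 cm, 1024×768 px, 85 Hz).  A pixel extent `n` along one axis subtends

    θ(n) = 2·atan(n·p / 2D)

where `p` is the physical pixel pitch (cm/px) on that axis.  Rather than
relying on unstated monitor dimensions, the pitch is **calibrated from a
known angle/extent pair**: the 190-px aperture diameter is taken to subtend
5.81° horizontally and 5.17° vertically, which fixes `p_h = 0.0438` and
`p_v = 0.0390` cm/px.  The axes therefore differ by ~12%, and all
conversions carry an explicit axis argument.  `deg_to_px∘px_to_deg` round
trips to < 1e-9 px.

The window/mask is a **hard-edged circle in pixel space** (no feathering —
the paradigm uses sharp apertures).  Membership is decided at pixel centers
with ties (distance exactly equal to the radius) counted inside; this makes
the central and peripheral renderings exact per-pixel complements, an
invariant the tests assert directly.  Coordinates are 0-based, origin at the
screen's top-left, x rightward, y downward.  Offline replay applies the mask
at each recorded gaze sample with zero display latency; modelling the
real-time update latency of a live eye tracker is out of scope.

## Session design

The stimulus catalog has four families (two of 8 species, two of 4), each
species with 12 exemplars: 288 images.  A session holds 144 experimental
trials — 48 per viewing condition, split 24 *same* (two exemplars of one
species) and 24 *different* (two species of one family) — in fully
randomized order, plus 6 practice trials.

Two structural decisions deserve note:

- **The image budget is exactly tight.**  144 trials × 2 images = 288, so a
  no-repeat session consumes the entire catalog.  Each species contributes
  3 same-trials (6 exemplars) and 6 different-trial slots (6 exemplars);
  within a family, different-trial pairs follow a round-robin schedule
  (6 of the 7 rounds for 8-species families; the 3 rounds cycled twice for
  4-species families), so every species is paired evenly.  Because nothing
  is left over, practice trials draw from a **practice-only reserve**
  (default 12 extra images, 4 pseudo-species × 3 exemplars) flagged
  non-experimental.
- **Seeded randomness is part of the contract**: the same seed reproduces
  the identical session, and trigger-dot positions are uniform over
  left/right/above/below.

Infeasible catalogs (odd species counts per family, exemplar counts not
divisible by four, trial counts not divisible by three conditions) raise an
error naming the violated constraint rather than silently degrading.

## Event detection

Gaze is sampled at a nominal 1000 Hz.  Angular speed is the Euclidean norm
of the per-axis central-difference derivatives, each axis converted to
degrees through its own calibration at the per-sample displacement scale
(where the tangent is effectively linear); acceleration is the derivative of
speed; endpoints use one-sided differences; **no smoothing** is applied.

A sample is saccadic when speed > 30 °/s **or** |acceleration| > 8000 °/s²;
a saccade runs from the first suprathreshold sample to the first sample at
which both measures are back below threshold.  Fixations are the maximal
inter-saccadic intervals (including the leading and trailing intervals).
This inter-saccadic reading is the standard operationalization; a literal
"period between a saccade onset and offset" would label the saccade itself.
A motion (minimum-amplitude) threshold of 0.0° means no amplitude veto; the
veto is implemented but disabled at that default, as is a minimum fixation
duration of 0 ms.

Event spans are contiguous — each event ends at the sample where the next
begins — so fixation + saccade + invalid durations sum exactly to the trace
duration (asserted to the sample).  Runs of invalid samples (blinks/track
loss) split events, belong to neither class, and receive no padding; valid
runs too short for kinematics (< 3 samples) are classed as fixation.
Detection is invariant to position offsets and time translation.

## ROI analysis

Each stimulus carries five labeled polygons (head, wings, body, tail,
feet) in image-frame coordinates.  A fixation is attributed **by its
centroid** (standard AOI practice): the first polygon containing the point
in the fixed priority order head > wings > body > tail > feet, with
boundary points inside; anything else is off-bird and excluded from both
numerator and denominator.  The priority order matters only for
hand-drawn overlapping maps; the synthetic maps are disjoint rectangles.

Proportion looking time divides each ROI's summed fixation duration by the
total on-bird duration (undefined — NaN, not zero — when nothing lands on
the bird).  The time course splits fixation durations **proportionally**
across 100-ms window boundaries (30 windows for the 3000-ms study display)
and renormalizes within each window; the proportional split makes the
on-bird-time-weighted aggregate of the windows reproduce the overall
summary exactly, which the tests assert to 1e-9.  Cross-observer
time-course similarity uses Pearson correlation over windows defined in
both courses (≥ 3 required).

## Behavioral pipeline

Responses live in a tidy trial table (participant, group, condition, trial
type, response, RT).  Preprocessing excludes, per participant, trials with
RT more than 3 SD **above** that participant's grand mean — a one-sided
trim, so fast outliers stay; zero-variance participants lose nothing.
Trimming precedes binning and all downstream analyses.

Sensitivity uses the loglinear-corrected d′,

    d′ = Φ⁻¹((H+0.5)/(n_same+1)) − Φ⁻¹((FA+0.5)/(n_diff+1)),

finite by construction even at perfect performance ("same" on a same trial
is a hit; "same" on a different trial is a false alarm).  Response bias
(criterion c) is exposed as a utility but is not part of the core analyses.

The RT-quintile analysis sorts each participant × condition cell's trials
from fastest to slowest **separately per trial type** (stable sort; ties
keep input order) and cuts each type into five rank bins, earlier (faster)
bins receiving the extra trial when counts are not divisible by five
(24 trials → 5,5,5,5,4).  Binning uses all trimmed trials, correct and
incorrect — necessary for bin-wise hits *and* false alarms to exist.  Each
bin's d′ comes from its own pooled confusion counts; per-condition d′
comes from the cell's pooled counts, never from averaging bin d′ (a
regression test guards the distinction).  Mean RT per condition uses
correct trials only; empty cells yield flagged rows rather than silent
drops.

## Inferential statistics

The split-plot ANOVA is implemented from first principles for balanced
complete designs with one between factor and up to two within factors.
After relabelling subjects within group, sums of squares for every
factorial stratum are computed by inclusion–exclusion over marginal means
(the closed form for balanced data) and nested terms are pooled
(SS[S(G)] = SS[S] + SS[G×S], and likewise for each within-factor error
term).  Every effect is tested against its proper stratum: group against
subjects-within-group; each within effect and its group interaction
against factor × subjects-within-group.  Unbalanced data raise an explicit
error — no Type-II/III fallback is attempted.  The tests verify the
decomposition against an independent projection-matrix oracle, against
pingouin for the one-within design, and against SS additivity.

Effect size is **generalized eta squared**: SS_effect divided by SS_effect
plus all subject-variance and error strata, the standard definition for
designs whose only measured factor is the subject.  No sphericity
correction is applied by default (reported dfs are uncorrected); a
Greenhouse–Geisser epsilon is available separately.

Welch's t-test is computed from summary statistics (mean, SE, n) with
Welch–Satterthwaite degrees of freedom on SE² with n−1 denominators.  The
minimal detectable Cohen's d solves power(d) = target on the noncentral-t
power curve of the two-sided two-sample test (noncentrality d·√(n/2)),
root-found to 1e-6; scipy's noncentral t underflows to NaN in the extreme
far tail, where the missing mass is numerically zero and is treated as
such.

## The synthetic observer

The simulator is the package's synthetic-data generator and encodes the
perceptual-field hypothesis directly.

**Gaze.**  Every trace starts on the trigger dot — placed 40 px outside the
450-px stimulus frame (≈ 8° eccentric), guaranteeing the first fixation is
off-bird — then alternates fixations and saccades at 1000 Hz.  Fixation
targets draw their ROI from the attraction distribution (defaults are the
empirical looking-time shares 44.28/23.24/17.05/7.79/7.65%, renormalized
from their printed sum of 100.01%) and a uniform point inside that
polygon; the ROI label is drawn once and only the point is resampled when
a jump would be under 25 px, keeping the label marginal exact.  Fixation
durations are lognormal (median 230 ms, σ = 0.35, clipped to 60–1200 ms);
saccades last 20–60 ms (duration increasing with amplitude) with
raised-cosine position profiles, so peak velocity always clears the
detection threshold and the detector recovers the generated fixation
sequence exactly on noise-free traces.  Gaussian position noise is
available but defaults to off.

**Evidence and responses.**  Each stimulus carries one diagnostic feature
per ROI at the polygon centroid, with weights equal to the attraction
shares (head most diagnostic).  During a fixation, information accrues at
`info_rate · Σ_f w_f · gain(e_f) · gate(e_f)`, with Gaussian gain
`exp(−e²/2σ²)` (an exponential profile is available behind a switch) and
an indicator gate: full view passes all features, central view only those
within 2.905° of gaze (the 95-px aperture radius under the horizontal
calibration — the field's vertical anisotropy is ignored), peripheral view
only those beyond.  The gates partition full view exactly:
ΔI(full) = ΔI(central) + ΔI(peripheral), tested to machine precision.
Eccentricity uses the horizontal calibration on both axes.  The observer
responds when cumulative information reaches the evidence bound (RT =
crossing time + 300 ms motor delay) or at the 2000-ms response deadline,
with accuracy Φ(d_eff/2), `d_eff = d_max·(1−exp(−I))`, an unbiased
criterion, and a 2% uniform lapse rate.  The generator applies condition
gating analytically instead of modelling the gaze-contingent display loop,
which is equivalent under zero display latency.

**Groups and defaults.**  Experts and novices differ in field width
(σ = 3.0° vs 1.5°) and asymptotic sensitivity (d_max = 3.5 vs 2.0);
per-participant parameters get lognormal jitter (sd 0.15).  The shared
defaults (info rate 4.5 s⁻¹, bound 1.5, deadline 2000 ms) were chosen once
so that (i) full-view RTs fall in the 1–2 s range, (ii) the deadline
genuinely binds in the slower conditions, giving full-view > peripheral-view
sensitivity within each group, and (iii) the peripheral cost is markedly
smaller for the wide-field expert — the qualitative group × condition ×
speed structure the analysis pipeline is designed to detect.  No
quantitative field-width estimates exist for real experts or novices; these
are free parameters, not fits.

**Cohorts and reproducibility.**  A cohort simulates 15+15 participants
(configurable, ≥ 2 per group) with full 144-trial sessions.  All
randomness flows from one master seed through `numpy` `SeedSequence` spawn
keys `(participant index, trial index, phase)`; study-phase traces are
regenerated on demand from those keys instead of being stored, and
regeneration is bit-identical.  The cohort also records, per trial, the
fixation durations and feature eccentricities that fed the response — the
sufficient statistics for **parameter recovery**: a grid-search maximum
likelihood over σ (13–25 geometric grid points over 0.5–10°), re-running
the capped accumulation to each trial's observed decision time and scoring
correctness.  Recovery preserves the expert > novice field-width ordering
in ≥ 95% of replicate cohorts.

**What the generator does and does not emulate.**  It reproduces the ROI
looking-time distribution, head-dominant feature diagnosticity, plausible
fixation/saccade kinematics, deadline-limited evidence accumulation, and
the expertise structure above.  It does **not** model temporal
non-stationarity of viewing (the target distribution is constant within a
trial, so ROI time courses are flat after onset and cross-observer
time-course correlations are weak, unlike real viewing with its early head
bias), saccadic main-sequence variability, microsaccades, pupil dynamics,
measurement noise or blinks (both available but off by default), or any
difference in eye movements between groups (by design: both groups share
the same gaze policy).  Passing pipeline tests on this generator therefore
validates the analysis machinery, not claims about human gaze behavior.

## Problem sizes in tests and the acceptance script

Tests run at the scale that makes their oracle exact or their Monte-Carlo
band comfortable: closed-form checks at printed precision; direction-only
simulation checks at 400–1500 trials; the ROI round trip at the full
15+15 × 144-trial cohort (tolerance ±1.5 percentage points, ~5 standard
errors of its Monte-Carlo wobble); recovery ordering over 100 replicate
cohorts of 2+2 participants, the smallest cohort the downstream statistics
admit.  The acceptance script re-simulates the full 15+15 cohort for the
ROI quantity and solves the power computation exactly; both derive every
random stream from the `--seed` argument.
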