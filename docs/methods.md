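# Methods

`postprime` analyzes self-initiated step-and-reach trials performed under
progressively more threatening surface-lubrication conditions (NL, LP, LL,
LB: no lubricant; lubricant under the planted leg; under the landing area;
under both).  The question the design addresses is how primed fear of
falling reshapes *preparatory* postural control — the anticipatory CoP/CoM
adjustments and muscle activity that precede the reach — and the
*compensatory* strategy that follows it.  The package implements the whole
measurement chain from raw laboratory channels to the statistical layer,
and ships a synthetic cohort generator with exact ground truth so that
every stage is testable without access to participant data.

## Signal conditioning

Kinematic channels (100 Hz) are smoothed with a 40-point Savitzky–Golay
filter and the quiet-stance DC offset is removed.  Conventions the package
fixes where the processing description leaves room:

* The 40-sample window is promoted to 41 samples — the centred
  least-squares fit requires an odd window.  Polynomial order is 3, the
  standard choice for kinematic smoothing.
* The DC offset is the mean of the first 0.5 s (quiet stance), not the
  whole-trial mean, which is contaminated by the movement itself.
* Edge handling is reflect padding.

EMG (2000 Hz) is processed in this exact order: 60 Hz notch (Q = 30) →
demean → full-wave rectify → zero-lag 4th-order Butterworth low-pass at
100 Hz.  "Zero-lag 4th order" is realized as a forward–backward pass of a
2nd-order design, so the *effective* order is 4; the alternative reading
(forward–backward 4th → effective 8th) is a common ambiguity and is stated
here explicitly.  Small negative values left by low-passing a rectified
signal are clipped to zero (the output is an activation envelope).
Envelopes are then normalized per participant × muscle to the maximum
amplitude over all of that participant's trials in all four conditions, so
normalized values lie in [0, 1] and CCI values in [0, 2].

## Event timeline

All metrics anchor to five events per trial: reach onset and target contact
(edges of an infrared beam channel), CoP onset (CoPon), landing-limb
unloading (StepOn) and landing contact (StepOff).  The source protocol
does not state its CoPon or unloading algorithms, so the defaults below are
standard posturography heuristics, all exposed in the `events:` config
section:

* **CoPon** — trigger when the net CoP (AP or ML, whichever first) leaves
  the quiet-stance mean by more than 3 baseline SDs sustained for 25 ms;
  the onset is then refined by a least-squares one-changepoint ("hinge")
  fit of the deviation over a window around the trigger (0.8 s back,
  0.1 s forward).  The refinement removes the threshold-crossing latency,
  which for a finite-rise shift in noise is otherwise tens to hundreds of
  milliseconds; `cop_refine: threshold` reports the raw crossing instead.
* **StepOn** — landing-limb vertical force first drops below 5 % of its
  quiet-stance value; **StepOff** — first subsequent loading above 5 % of
  body weight; both sustained 5 ms.
* Net CoP is the vertical-load-weighted average of per-plate CoPs computed
  from forces and surface moments about each plate centre.

Events are reported on the force-plate clock (1000 Hz); kinematic metrics
interpolate to event times.  Axis conventions used everywhere: AP = +x
toward the target, ML = +y leftward, time zero at recording start, 0-based
samples.  Step length/width are the AP/ML distances between the support
and landing malleoli evaluated at StepOff (foot flat at landing).

## EMG metrics

Muscle onset is the first sample whose envelope exceeds baseline mean +
7 SD and stays above threshold for the following 50 ms.  The baseline
window is the first 0.5 s of the trial (quiet stance precedes every event
by construction in the generator; configurable for other recordings).
"7 SD of average baseline activity" is read as mean + 7·SD; a reading of
7 × mean is dimensionally inconsistent with an SD-based phrase.  Onsets
are reported relative to reach onset (negative = preparatory).  Muscles
with no detected onset are excluded from onset statistics, not imputed;
visual confirmation of onsets is replaced by automated QC flags
(onset implausibly early/late relative to the event timeline).

The co-contraction index of an agonist–antagonist pair over a window is

    CCI = mean over samples of  min(a, b) / max(a, b) × (a + b)

with zero-activity samples contributing 0.  The index is symmetric and
amplitude-weighted by design — doubling both envelopes doubles the CCI —
which is why normalization precedes it; the plain ratio `mean[min/max]` is
available as `cci.method: ratio`.  The exact published formula behind the
index is not reproduced in the protocol text, so both variants remain
configurable.  Four phases are evaluated: (i) early, 1.5–0.5 s before
reach onset; (ii) preparatory, the 0.5 s before reach onset; (iii)
movement, the 0.5 s after; (iv) termination, the 0.5 s before target
contact.  Phases i–ii are tagged preparatory, iii–iv compensatory.
Default pairs: rectus abdominis vs erector spinae (trunk) and tibialis
anterior vs gastrocnemius (shank), bilateral; the pair table is fully
configurable because the original pairing is not stated.

## Movement metrics

* Preparatory interval [CoPon, StepOn]: per-axis CoM excursion (max −
  min) and peak |acceleration| (second central difference of the smoothed
  position — chosen over an additional differentiation filter because the
  position is already Savitzky–Golay smoothed).  The peak (not the mean)
  of the acceleration is used; the alternative is not stated in the
  protocol.
* Movement interval [CoPon, target contact]: total per-axis CoM excursion
  and peak-to-peak excursions of seven joint angles (support-limb ankle,
  knee, leading-limb hip, lumbar, thorax, shoulder, elbow).  Whether the
  "duration of movement" ends at target contact or trial end is not
  stated; target contact is the default (`movement.movement_end`),
  covering the preparatory and reach phases.

## Statistical layer

Per dependent variable, trials are averaged to one value per participant ×
condition and a two-way mixed repeated-measures ANOVA (Condition ×
AgeGroup) is computed from the classical sums-of-squares decomposition;
the decomposition is verified internally (components must sum to the total
to 1e-8 relative).  Effect sizes are partial eta squared,
η²p = F·df1/(F·df1 + df2).  Sphericity is tested with Mauchly's W on the
pooled within-group covariance; when rejected at 0.05 the
Greenhouse–Geisser ε multiplies both within-subject degrees of freedom
(Mauchly is the conventional gate; the protocol only says the correction
was applied "where violations were observed").

The family-wise correction is applied literally as published: a single
divided alpha, `alpha_adj = 0.05 / (#DVs × 2)` per family (condition main
effect + interaction per DV) — for a 5-DV family, p < 0.005.  This is a
Bonferroni bound rather than a sequential Holm procedure; a true
sequential Holm step-down is available as `stats.method:
holm_sequential`, and the discrepancy is deliberate and documented.
Significant omnibus effects trigger Bonferroni post hocs: paired t-tests
across conditions within each group (multiplier C(4,2) = 6) for condition
effects, and independent t-tests between groups per condition for
interactions.

A known source inconsistency: four of the published η²p values (0.597,
0.585, 0.402, 0.391) do not satisfy η²p = F·df1/(F·df1+df2) at the printed
df = (1, 18); they are flagged here and not used for validation.  The five
internally consistent triplets are (36.463; 1.845, 29.518; 0.695),
(31.343; 3, 48; 0.662), (11.06; 1, 18; 0.381), (11.630; 1, 18; 0.392) and
(19.020; 1, 18; 0.514).

## Synthetic cohort generator

The generator emulates the study design: 10 participants per age group
(YOUNG, OLDER), four blocked conditions NL → LP → LL → LB, 3 trials per
block, 8 s per trial, EMG at 2000 Hz, force plates at 1000 Hz, kinematics
at 100 Hz, one binary beam channel.  Streams are generated at their native
rates to force the pipeline to handle multi-rate alignment.  A single
master seed expands through `numpy.random.SeedSequence` keys per
participant / block / trial, giving bit-reproducible cohorts with
independent trials.

Every scalar of a trial is drawn from
`baseline + condition + group + interaction + N(0, subject_sd) +
N(0, noise_sd)`; VAS scores are drawn once per condition block (scales are
administered before each block) and clipped to [0, 100].  `noise_scale`
multiplies all measurement and trial noise jointly; between-participant
heterogeneity is retained at `noise_scale = 0` so that noise-free cohorts
remain statistically analyzable.

Default effect directions mirror the reported findings: VAS fear ratings
climb ~15 mm per condition step; step width (+0.03 m at LB), lumbar
excursion (+8°) and hip/thorax excursions increase while support-ankle
excursion decreases (−5°) under lubricated surfaces; total ML CoM
excursion carries a group × condition interaction (+0.03 m for YOUNG at
LB); rectus abdominis and gastrocnemius onsets shift from before reach
onset (YOUNG) to after it (OLDER, +0.13–0.14 s); and in OLDER × LB the
step follows rather than precedes reach onset (reach lag −0.10 s).
Magnitudes are plausible laboratory values chosen once for the generator,
not fitted to any dataset.

Channel constructions are deterministic given the drawn scalars:

* **Force/CoP** — the landing-limb vertical force declines linearly from
  half body weight to zero starting at CoPon, crossing 5 % of its quiet
  load exactly at StepOn; since the net CoP of a two-plate stance is the
  load-weighted mean of the foot positions, the same mechanism yields an
  ML CoP ramp starting exactly at CoPon.  A linear decline (rather than a
  sigmoid) is used deliberately: CoP shift and unloading are one physical
  process, the threshold crossings are exactly defined, and the hinge
  onset refinement is exact on it at zero noise.  Reloading of the landing
  zone crosses 5 % of body weight exactly at StepOff.
* **CoM** — a half-cosine of the configured preparatory excursion over
  [CoPon, StepOn], a short hold, then a quintic ramp to the configured
  total excursion; monotonicity makes peak-to-peak recovery exact up to
  filter effects.  The APA phase lasts 0.55 s by default (within the range
  reported for step/gait initiation); this also keeps the preparatory
  excursion long relative to the 0.4 s smoothing window, so round-trip
  recovery is within 1 %.  The analytic preparatory-acceleration peak of
  the half-cosine, A/2·(π/T)², is recorded as ground truth; the
  Savitzky–Golay window attenuates the measured peak by roughly a third,
  uniformly across conditions (the filter is linear), so condition effects
  and their signs are preserved even though absolute accelerations are
  conservative.
* **EMG** — each muscle's activation is an envelope with a 10 ms
  half-cosine rise (ground-truth onset = ramp start) riding a
  deterministic ±1 square-wave carrier at 250 Hz, plus Gaussian baseline
  noise (SD 0.1 of burst amplitude → burst SNR 10).  Because
  |carrier| = 1, full-wave rectification recovers the envelope exactly,
  which makes onset and CCI ground truth well defined; the more common
  amplitude-modulated-Gaussian surrogate leaves the max-normalization with
  an extreme-value bias that has no closed-form truth.
* **Kinematics** — joint angles ramp monotonically by their configured
  peak-to-peak excursion over the movement interval; malleoli trajectories
  complete the swing early enough that landing positions sit on a
  constant plateau at StepOff (exact step geometry after smoothing).

What the generator does *not* emulate — and therefore what passing tests
do not establish about real recordings: motion and electrode artifacts,
EMG cross-talk and nonstationary interference, actual slips or falls and
aborted trials (all synthetic trials complete the task, as did all
analyzed trials in the study), soft-tissue marker noise, and any
musculoskeletal dynamics linking the channels (forces, CoM and EMG are
kinematically consistent but not dynamically simulated).

## Numerical choices and degenerate inputs

* Onset detection with a perfectly flat (SD = 0) baseline and a nonzero
  signal raises a degenerate-baseline error; a flat envelope returns
  "no onset".
* An all-zero EMG channel fails normalization with a dead-channel error.
* A preparatory interval with fewer than 3 kinematic samples yields
  missing metrics plus a QC flag.
* Mixed ANOVA with zero error variance raises unless every effect is also
  zero (then F = 0); missing participant × condition cells are reported by
  name.
* Greenhouse–Geisser ε is clipped to [1/(k−1), 1]; a singular contrast
  covariance counts as maximal sphericity violation.
* All-identical post hoc samples return p = 1.

## Problem sizes used by the validation suite

The shipped suite generates cohorts at the full study design (2 × 10
participants × 4 conditions × 3 trials) for end-to-end checks, 500
metric-level null cohorts for Type-I calibration, 500 null EMG channels
for false-positive calibration, and 50–200 randomized small designs for
the oracle-equivalence checks.  These sizes were chosen to keep Monte
Carlo error well below the tolerances being asserted.

## Known limitations

* The statistical layer implements the published divided-alpha rule; a
  pre-registered sequential Holm analysis would be slightly more powerful.
* CCI ground truth is defined for the synthetic carrier model; on real
  EMG the amplitude-weighted CCI inherits normalization noise.
* The CoPon and step-event thresholds are heuristics; on real force-plate
  data they should be tuned per laboratory and are exposed in config.
* No inverse dynamics, marker-level synthesis, or slip/fall modeling.
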