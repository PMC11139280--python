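# Methods

## Signal model

Nodding is treated as one-dimensional vertical motion of the head. The raw
observable is the nose-tip keypoint of a 70-point face model together with
the collarbone/neck (index 1) and mid-hip (index 8) keypoints of a 25-point
body model, each an (x, y, confidence) triple per video frame. The analysis
signal is

    y(t) = −(nose_y(t) − collarbone_y(t)) / s,

where `s` is the signer's hip-to-collarbone distance and the minus sign
converts image coordinates (y grows downward) to an up-positive trace. The
division by `s` yields *normalized pixels* (npix), making amplitudes and
velocities comparable across signers and camera distances. `s` is the median
over all frames in which both scale keypoints are confident; a per-frame
option exists but the median is the default because per-frame division
injects scale jitter into the vertical trace while posture changes within a
seated conversation are small.

Samples with confidence 0 (missing detections) and dropped frames are
linearly interpolated from the nearest valid neighbors *before* filtering —
zero-phase filters propagate edge artifacts both ways, so holes must be
closed first — and the interpolated fraction is reported per trajectory so
heavily reconstructed spans can be screened.

## Filtering and extrema

Pose-estimation jitter is suppressed with a second-order Butterworth low-pass
filter applied forward and backward (`scipy.signal.filtfilt`), giving zero
phase lag: peak and trough times are not shifted by smoothing, which matters
because measures are computed inside externally annotated time spans. The
default cutoff is 20 Hz at 50 fps. The filter is applied once per recording,
never per span, so filter transients never coincide with nod boundaries.

Peaks are local maxima with topographic prominence ≥ 0.1 npix and pairwise
separation ≥ 5 frames (100 ms at 50 fps); troughs are the same on −y. The
test suite pins this to an exhaustive brute-force implementation of the
prominence definition on every trajectory up to 500 samples.

A note on the prominence default: 0.1 npix is larger than the median nod
amplitude observed in natural signing (≈ 0.02–0.09 npix), so most nods
retain no extrema at all and the amplitude computation falls back to the
span's raw `max y − min y`, with a flag recorded per nod. Both the threshold
and the fallback are deliberate defaults: the threshold is the established
value in prior head-movement work and is fully configurable
(`peaks.min_prominence_npix`); the fallback keeps amplitude defined for
small nods. Peak counts under this threshold are near zero and should be
interpreted accordingly (or recomputed at a lower threshold).

## Per-nod measures

- **Duration**: annotated offset minus onset, in seconds. Pose-independent.
- **Velocity**: mean absolute vertical displacement between adjacent frames
  inside the span, times fps — i.e. the time-averaged |dy/dt| in npix/s.
  The per-second scaling is written into every output table's metadata
  (`velocity_unit=npix_per_second`) so a per-frame convention can be
  reconstructed exactly by dividing by fps.
- **Maximal amplitude**: highest peak minus lowest trough within the span
  (fallback above). This is a range measure: if the resting head position
  drifts during a long nod, it reports the total excursion, not the largest
  single peak-to-trough swing.

All measures are invariant under uniform scaling of pixel coordinates
(property-tested), because the npix normalization cancels camera geometry.

## Annotation scheme and derived classifications

Nod form uses the five-tag vocabulary sn / ln (single small/large), hnn /
lnn (many small/large), mn (mixed); function is feedback / affirmation /
other; turn-taking is PR (passive recipiency) vs TI (turn initialization),
coded only for feedback and affirmation nods. The validator enforces the
segmentation rule that two nods separated by less than 300 ms should have
been one continuous-nodding annotation, flags unknown tags, and flags
single-nod tags of implausible length (a held up-position is a head tilt,
not a nod — only a human can decide, so this is a warning, not an error).

TI is operationalized as: a gloss span of the nodder starts within 300 ms of
the nod's offset (either side, so signing that overlaps the nod's tail
counts) *and* constitutes a turn — it is followed by at least one further
gloss span, or itself lasts ≥ 1 s. The second clause exists because a lone
response token (a single YES) accompanies passive recipiency rather than
claiming the floor; both clauses are configurable, and the bare 300 ms rule
is available via `require_turn_constituting=False`.

Co-occurrence with manual and mouth activity uses any strictly positive
temporal intersection, with no minimum-overlap fraction (the convention of
the annotation tooling this scheme comes from). When both a lexical gloss
and a gesture gloss intersect a nod, the record is labeled lexical; gesture
glosses are recognized by the corpus glossing convention ($-prefixed
labels), mouth gestures by the `[MG]` tag. The precedence is fixed but the
tiers are retained, so the alternative reading is recomputable.

## Inter-annotator reliability

Two independent segmentations of the same recording are first matched
one-to-one: candidate pairs must overlap by at least 61% (the conservative
threshold of the modified-kappa methodology), where the overlap fraction is
intersection over union — symmetric in the annotators, which the reported
statistics inherit; `shorter` and `longer` denominators are available and
logged. Matching is greedy in decreasing overlap (reproducible,
near-optimal on sparse tiers); an optimal assignment solver sits behind a
flag. On matched pairs the package reports raw agreement, Cohen's kappa
over the tag vocabulary, and mean overlap; a second kappa adds every
unmatched span as a disagreement with an explicit "unmatched" category, so
segmentation disagreement is penalized rather than silently discarded.

## Statistics

Analysis restricts to feedback/affirmation nods. The three kinematic
variables are z-scored (ddof = 1); observations outside
`[Q1 − 5·IQR, Q3 + 5·IQR]` on *any* variable are removed whole (computed
once, not iterated). Quartiles use the Hazen convention by default; the
convention is configurable and recorded with the fences.

Two-sample comparisons report Welch's t (equal-variance t selectable) and
the Wilcoxon rank-sum test, with the sum-of-ranks statistic of the first
group alongside Mann-Whitney U; signs are always group A minus group B and
stated in the output. Pearson correlations carry Fisher
variance-stabilized CIs. The bootstrap of median differences resamples both
groups with replacement, is percentile-based, and requires a seed.

The core model is a binomial GLMM: nod function (affirmation = 1) on
z-scored predictors with a Gaussian random intercept per signer. The
marginal likelihood integrates the intercept out with 25-node Gauss–Hermite
quadrature and is maximized with L-BFGS-B on (β, log σ_u); standard errors
come from the numerical Hessian, per-signer adjustments are posterior means
of the random intercept, and the quadrature order and optimizer are recorded
in every fit. With a single signer the model collapses to plain logistic
regression with σ_u = 0. The fitter is cross-checked in the test suite
against an independent quadrature implementation (R lme4, nAGQ = 25) to
~1e-3 on coefficients, and calibrated by simulation: the likelihood-ratio
test of a pure-noise predictor rejects at the nominal 5% rate (within
[0.02, 0.09] over 200 null simulations), and a simulated 1.0 per-SD slope
is recovered within 10% on average at 30 signers × 30 nods. Model
comparison is the likelihood-ratio χ² between nested fits on identical data.

## Synthetic data

The generator emulates the structures the pipeline consumes, with defaults
fixed at the observed operating point of natural DGS conversation:

| parameter | default | meaning |
|---|---|---|
| fps | 50 Hz | corpus video frame rate |
| n_signers × nods_per_signer | 24 × 27 = 648 | corpus-size session |
| function mix | 64 / 13 / 23 % | feedback / affirmation / other |
| median amplitude | 0.025 npix (σ_log 0.6) | small-nod regime |
| median frequency | 1.4 Hz (σ_log 0.25) | nod cycle rate |
| affirmation offsets | +0.8 log-amplitude, +0.8 log-velocity | affirmation larger & faster |
| TI frequency offset | +0.35 log | turn-initiating nods quicker, shorter |
| affirmation extra cycles | +0.7 (Poisson mean) | affirmative nodding spreads over the response |
| signer intercept sd | 0.8 log-odds | between-signer affirmation propensity |
| manual co-occurrence | 87% affirmation / 35% feedback | gloss overlap probabilities |
| turn initialization | 86.7% affirmation / 27.8% feedback | turn annotation probabilities |
| jitter | 0.003 npix/frame/keypoint | pose-estimation noise (~1.7 px) |
| dropped frames / low confidence | 1% / 0.5% | recognition failures |

A nod is a windowed sinusoid: `y(t) = (A/2)·sin(2πft)` under a Tukey window
(taper fraction 0.2) whose flat interior covers every interior extremum, so
the core peak-to-trough excursion equals the scripted amplitude within 2%
while the head leaves and returns to rest smoothly. Sinusoids are chosen
precisely because they admit closed-form truths (peak-to-trough `A`, mean
speed `2Af`), enabling exact end-to-end recovery tests. Ground truth is
tabulated per nod from the clean pre-jitter signal using the same
frame-inclusion convention as the measurement stage.

The combination of TI nods being faster-cycled and affirmations spreading
over more cycles reproduces the qualitative pattern of natural data:
velocity and amplitude separate the functions strongly, duration does not,
while within feedback nods duration and velocity separate PR from TI.

What the generator does *not* emulate: temporally correlated pose noise
(real keypoint jitter is autocorrelated; independent Gaussian noise is the
harsher case for a smoothing stage), head rotation and non-nod head
movements, multi-person scenes, and annotator boundary uncertainty in the
primary tiers (a separate `perturb_annotator` simulates a second annotator
for reliability work). Passing recovery tests on this generator therefore
demonstrates correctness of the measurement chain, not robustness to every
artifact of real recordings.

Noise behavior, quantified: at zero jitter every nod's amplitude and
velocity are recovered within 5% (duration is exact by construction). At a
realistic 0.003–0.005 npix jitter, the span range statistic is biased
upward — the median relative amplitude error reaches tens of percent for
small (≈ 0.02 npix) nods, because the residual noise excursion after any
filter that preserves nod frequencies (≤ ~4.5 Hz) is of comparable size.
Large and small nods remain well separated, and group contrasts remain
detectable; absolute amplitudes of small nods in noisy pose data should be
read as upper bounds. This is a property of range-based amplitude on noisy
trajectories, not of the generator.

## Numerical choices

- Quartiles: Hazen (`numpy` method `"hazen"`); configurable, logged.
- Filter feasibility: trajectories must exceed the filtfilt padding length
  (3 × (order + 1) samples); cutoff must be below Nyquist.
- Span slicing: a frame belongs to a nod iff its timestamp lies in
  `[start, end]`; spans shorter than two frames are errors.
- Extrema ties: separation thinning keeps the higher peak, breaking exact
  height ties toward the earlier index.
- GLMM: 25 quadrature nodes (matches lme4 nAGQ = 25 to ~1e-3 at σ_u ≤ 1.5);
  LRT statistics within −1e-4 of zero are clamped to zero, more negative
  values raise (a convergence failure, never silently reported).
- Bootstrap and simulation seeds are mandatory arguments; the acceptance
  script derives per-stage sub-seeds from one master seed via
  `SeedSequence`.

## Problem sizes

The default test-suite and acceptance-script sizes — sessions of 4–24
signers with 12–27 nods each, 200 null simulations, 100 recovery
replicates, 25-node quadrature, 2000–5000 bootstrap draws — were chosen so
the full validation cycle completes in well under a minute each while
keeping Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- Velocity is reported in npix/s only; comparisons with studies reporting
  per-frame displacement require dividing by fps (the metadata records the
  unit).
- The turn-initialization rule depends on gloss-tier completeness; corpora
  that under-annotate addressee signing will under-detect TI.
- Amplitude is a range statistic (see above); peak-to-adjacent-trough
  amplitude is not implemented because noisy intermediate extrema make it
  ill-defined at realistic jitter.
- The GLMM supports a single random intercept (per signer), not random
  slopes.
- Reliability statistics depend on the chosen overlap denominator and
  matching order when tiers are dense; both choices are recorded in the
  output to keep results interpretable.
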