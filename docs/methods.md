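# Methods

This note documents the models, defaults and numerical choices behind
`oculonet`, and what the synthetic cohort does and does not establish
about real recordings.

## Task designs

Both oculomotor tasks run 80 trials.  Anti-saccade (AS): a peripheral
stimulus appears left or right at 15° eccentricity, each side 40 times in
pseudorandom order; the instructed response is a saccade to the mirror
position, and a saccade toward the stimulus is a reflexive error.
Go/NoGo (GnG): the fixation cross jumps to one of eight peripheral
locations while a green (Go: saccade to it) or red (NoGo: hold fixation)
cue appears centrally; each cue colour is used 40 times and each location
10 times.  The eight locations form a diamond; the exact geometry is not
standardised, and we place the four vertices at 15° on the axes with the
four edge midpoints at (±7.5°, ±7.5°).  Fixation intervals are uniform on
2000–4000 ms, intertrial gaps on 2000–3000 ms.

## Event detection

Gaze positions (degrees of visual angle, 250 Hz) are smoothed with a
5-sample centred moving average.  Angular speed comes from central
differences (one-sided at segment edges).  Saccades are maximal runs with
speed ≥ 30 °/s lasting ≥ 12 ms; remaining spans are grouped into
fixations by the classical dispersion rule — a window of ≥ 50 ms whose
dispersion (range in x plus range in y, on smoothed positions) stays
≤ 1.0° is greedily extended.  These operating points are the standard
I-VT/I-DT values for 250 Hz data; commercial detectors do not publish
their constants, so all five are exposed as `DetectionParams`.  Samples
flagged invalid split events and nothing is interpolated by default
(optional linear fill for gaps ≤ 2 samples).  Dispersion is evaluated on
*smoothed* positions: at realistic fixation noise the raw range over a
one-second window already exceeds 1°, and smoothing restores the
classical behaviour without changing saccade timing.

## Trial scoring

The *primary saccade* of a trial is the first detected saccade after
stimulus onset with amplitude ≥ 2° (the amplitude gate rejects noise
blobs and microsaccades).  Its latency (onset − stimulus onset) must fall
in [80, 900] ms; anticipatory or late saccades discard the trial
regardless of direction.  AS direction is the sign of the horizontal
displacement; GnG direction must match the stimulus bearing within
±22.5°, half the 45° angular spacing of the eight locations, so each
location owns a disjoint sector.  A Go trial without a saccade is scored
a miss and counts against accuracy (a failure to move is an incorrect
trial); a NoGo trial is correct unless a qualifying saccade heads toward
the stimulus.  Performance accuracy (PA) is correct/total where the total
excludes discarded trials by default, so PA measures decision quality;
the alternative denominator (including discards) is a switch.  Subject
summaries report median latencies over non-discarded trials; error-latency
medians are missing (not zero) for subjects without errors, and the
network fit handles them pairwise-complete.

## Statistics

Student's t is the pooled-variance form by default (Welch by flag), the
variance F-test is two-sided (p = 2·min(tail, 1−tail)), Kruskal–Wallis
uses midranks with tie correction and a χ² reference, and Pearson's p
comes from t = r√((n−2)/(1−r²)).  Influence diagnostics for the simple
regression of median latency on accuracy flag an observation when any of
the package-standard cutoffs trips: leverage > 3p/n, |standardized
residual| > 2, Cook's D above the median of F(p, n−p), or
|DFITS| > 2√(p/n) (p = 2 parameters).  Flagged subjects are excluded
before the accuracy–latency correlations, mirroring the analysis order of
the study design this package models.  Exact-fit regressions define the
residual-based measures as zero.

## Synthetic cohort

The generator reproduces the study conditions: 93 patients and 41
controls by default.  Each subject's 12-measure profile (six cognitive
scores, four median latencies, two error proportions) is drawn from a
Gaussian copula whose target Pearson correlation matrix is the 12×12
matrix assembled from the packaged patient tables (used for both groups;
no control-group correlation structure is published).  Margins:

* cognitive scores and latency medians — normal, with the published
  means/SDs (impossible negatives clipped at zero; the clip mass is
  negligible at these means);
* error proportions — logit-normal, fit to the published median and
  quartiles (ASEs: median 0.10, quartiles 0.05/0.263 for patients;
  GnGEs = 1 − NoGo accuracy).  Control Go accuracy prints at ceiling, so
  its quartiles are pulled just inside the open unit interval
  (0.975, 0.995, 0.999) to admit a logit fit.

Because a monotone non-linear margin attenuates Pearson correlation, the
latent normal correlation of every pair involving a non-linear margin is
solved numerically (Gauss–Hermite quadrature + root finding) so that the
*output* Pearson correlation equals its target — the standard
Pearson-matching NORTA construction.  The assembled target matrix is
already positive definite (smallest eigenvalue 0.216); if a user-supplied
target is not, it is repaired by eigenvalue clipping at a small floor
followed by renormalisation to unit diagonal.

Published latency SDs are trial-level, pooled over all trials; the split
into between-subject (SD of per-subject medians) and within-subject
variance is not reported, and we take an equal split (each component
SD/√2), exposed as `between_variance_fraction`.  Trial latencies are
shifted lognormal (floor 80 ms) parameterised by mean and SD, with the
subject's drawn median as the mean of their own distribution.  Trial
outcomes are Bernoulli: correct with the subject's accuracy, otherwise an
error; trials whose correct response is a saccade can additionally be
missed (default 2%, a rate the source material mentions but does not
quantify).  Error saccades draw from a faster distribution than correct
ones, matching the published means.

Gaze traces embed the outcome: white isotropic positional noise (default
SD 0.15°) around fixation, then — when the outcome includes a saccade — a
raised-cosine displacement of the commanded amplitude beginning at
stimulus onset + latency, with a main-sequence duration of
2.2 ms/° × amplitude + 21 ms.

**What the simulator does not emulate**: pupil size, blinks, head
movement, calibration drift, saccade undershoot/corrective saccades, and
any dependence of error-latency distributions on error subtype.  Passing
round-trip tests therefore demonstrate that the detector and scorer
recover *this* generative model's ground truth at realistic noise; they
do not certify performance on real tracker artifacts.  Likewise, the
subject-level accuracy in the trial simulator derives from the drawn
error proportions (AS accuracy ≈ 1 − ASEs − miss rate), which is the
consistent choice for the network measures but implies somewhat higher
AS accuracy than the published accuracy quartiles, whose denominator
conventions for discards are not recoverable.

## Network model

`CorrelationNetworkModel.fit()` computes pairwise-complete Pearson r, p
and n for all 66 pairs of the 12 measures (≥ 3 complete pairs required;
otherwise the pair is left missing with a warning).  The *full* network
takes an edge wherever p < α (default 0.05); built from printed tables
the significance codes gate edges instead, and marginal (p < 0.1) codes
are excluded at α = 0.05 — the reading that exactly reproduces the
published verbal edge lists, which an inclusive p < 0.1 rule would
contradict.  The *thresholded* network takes an edge wherever |r| is
strictly greater than τ (default 0.4), applied to the printed two-decimal
coefficients for fixture runs.  One printed inconsistency is documented
rather than resolved: the source text describes DS as connected to all
other cognitive functions in the thresholded graph, but its printed
correlation with TMT is 0.39 < 0.4; we follow the table and the strict
threshold.  Centrality is degree — the only index the analysis uses —
with a cross-domain variant restricted to opposite-domain neighbours, and
ties returned as sets.  Patients-only data enter the network by default
(`group` filter).

## Problem sizes and reproducibility

All randomness flows from explicit seeds (NumPy `SeedSequence` spawning
per stage and subject); identical config + seed reproduces every artifact
byte-for-byte.  The test suite and the acceptance script choose problem
sizes that make their checks sharp but quick: correlation recovery at
n = 5000 subjects (tolerance ±0.05 per cell) and n = 93 (the patient-group
size, tolerance 3 standard errors per pair — across 66 simultaneous pairs
up to two chance exceedances under a 4 SE cap are tolerated, since even a
perfectly calibrated generator exceeds a per-pair 3 SE bound somewhere in
roughly one run of six); type-I-error calibration over 10,000 null
replicates at n = 30; and the detect→score round trip over 1,000 trials
at the 0.3° noise ceiling, where ≥ 99% label agreement is required.
End-to-end pipeline tests run a reduced cohort (6 patients, 4 controls)
with full gaze synthesis; the statistical behaviour of the pipeline does
not depend on cohort size, only on the per-stage contracts tested at
scale elsewhere.

## Known limitations

* The detector's constants are *decisions*, not a reconstruction of any
  proprietary implementation; on real data they should be tuned against
  hand-labelled events.
* The copula calibration targets the patient tables for both groups;
  control-group network claims are therefore out of scope.
* No partial-correlation or regularised network estimation, no bootstrap
  edge stability, no multiple-comparison correction (none is used in the
  reproduced analysis), and no attempt to reproduce patient-level group
  statistics that require the unavailable raw recordings.
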