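# Methods

This note documents the models implemented in `visint`, the default
parameter values and why they were chosen, what the simulated observers
do and do not emulate, and the numerical choices that matter for
reproducibility.

## Stimuli

**Gabor patches.** Each element is a cosine carrier times an isotropic
Gaussian envelope on a normalized luminance scale with mean 0.5.
Orientation is measured in degrees clockwise from vertical (0 = vertical
stripes). The envelope SD σ and the half-amplitude full bandwidth *b* (in
octaves) of the carrier at frequency *f* (cycles/degree) are related by

    σ = k·(2^b + 1) / (f·(2^b − 1)),   k = √(2 ln 2) / (2π),

which makes the two parameterizations used by the displays internally
consistent: (b = 1.14, f = 3.0) ⇒ σ ≈ 0.166° (0.16° to two truncated
decimals) for the collinear task, and (b = 1.2, f = 4.6) ⇒ σ ≈ 0.104°
(0.1° rounded) for the contour task. Patches are rendered over a ±4σ
support (the envelope is < 3.4 × 10⁻⁴ beyond, visually lossless);
deviations from mean luminance add where elements overlap and the frame
is clipped to [0, 1] at the end. Carrier phase defaults to 0 (cosine,
even-symmetric); the source experiments do not state phase, so this is a
package choice. The default degree-to-pixel scale is 49 px/°,
corresponding to a 1600-px-wide display of ≈40 cm at 70 cm viewing
distance; it is configurable because the physical screen size of the
original apparatus is not recorded. Photometric calibration, gamma
correction and bit-depth dithering are explicitly out of scope: luminance
lives on the normalized [0, 1] scale.

**Collinear-facilitation displays.** A central vertical target at the
requested Michelson contrast, flanked at (0, ±3λ) — 1° at 3 cpd — by two
60%-contrast Gabors sharing one signed orientation offset (both +θ; the
mirrored variant is not used, matching the canonical depiction of this
paradigm). The baseline condition has no flankers. The target-absent
2IFC interval is the same frame with target contrast 0; frames for the
two intervals differ only inside the target's patch support.

**Contour-integration displays.** A 33 × 24 invisible grid (792 cells,
≈1° cells at the default geometry) with exactly one 100%-contrast Gabor
per cell. Background cells get an orientation uniform on [−90°, 90°) and
an integer positional perturbation drawn uniformly on [−11, 11] pixels
per axis (the symmetric-integer law; the original description gives
magnitudes on [0, 11] with unstated sign handling, and the symmetric law
avoids double-weighting zero). Contour cells are centered exactly and
carry base orientation + a jitter draw uniform on [−J, +J] for the
condition's range J ∈ {0, 15, …, 90}; the comparison (contour-absent)
interval replaces the contour orientations with uniform [−90°, 90°)
draws. Both intervals of a trial are generated from one seed so their
backgrounds are identical; only contour-cell orientations differ.
Orientations are wrapped to [−90°, 90°) (orientation is defined mod 180°).

Contour cell maps: *lines* = two 10-cell vertical runs in the columns
nearest ±5° eccentricity, vertically centered; *square* = the identical
vertical runs plus 9-cell horizontal runs one row above and below and
four ±45° corner cells (42 cells); *windmill* = four straight arms in an
open pinwheel arrangement plus two filler cells to match the square's 42
elements. The windmill geometry is not quantified in the source
description (a figure only), so a plausible layout is frozen in
`src/visint/data/windmill_cells.txt`; tests treat it as a fixed fixture.

## Threshold procedures

**Psi method (adaptive, contrast task).** Grid posterior over Weibull
(α, β) with γ = 0.5 fixed by 2IFC and δ = 0 fixed (this keeps the
estimated α exactly at the 81.6% correct level; a free lapse is a
documented non-goal). Defaults: α log-spaced on [0.002, 0.5] (61 points),
β log-spaced on [0.5, 16] (31 points), 41 log-spaced candidate contrasts
on [0.002, 0.8], uniform prior. These grids are package choices — the
original toolbox configuration is unrecorded — and are wide enough to
cover every threshold the default observer profiles can produce. Each
trial selects the candidate minimizing expected posterior entropy
(exact enumeration over candidates, computed via three matrix products
against precomputed likelihood tables; ties break toward the lower
contrast), then applies Bayes' rule on the grid. The posterior is stored
in log space and renormalized by log-sum-exp each trial. The running
estimate is the posterior mean of log α, exponentiated, because
thresholds are ratio-scaled quantities.

**Constant stimuli (contour task).** Binomial maximum likelihood of the
decreasing logistic with γ = 0.5 fixed and lapse free but bounded in
[0, 0.06], following common practice for this fitting framework (whether
the original analysis fixed or freed the lapse is unrecorded). The
independent variable is the nominal jitter-range maximum of each
condition, not the realized per-trial jitter, because the analyses are
defined per condition. Optimization is L-BFGS-B from a fixed list of ten
starting points (five midpoints across the tested range × two spreads),
so fits are exactly reproducible without seeds; tests verify the fitted
likelihood never falls below a coarse grid-search oracle. Data at or
below chance (or perfect) at every level are flagged non-identifiable
rather than fitted.

## Simulated observers

Observers are parametric: they respond to the *nominal* stimulus level
through their psychometric function, as Bernoulli draws. They are not
image-computable — nothing about the rendered pixels feeds back into
behaviour — so passing tests show that the estimation and analysis
pipeline recovers the generating parameters, not that any particular
image-level mechanism holds.

A group profile holds means and between-subject SDs for: the baseline
contrast threshold (truncated normal on (0, 1]); facilitation in dB per
flanker offset (independent normals per offset — negative draws mean
suppression and are legitimate); jitter tolerance per shape (joint normal
with exchangeable between-shape correlation, truncated to (0, 90) by
rejection); plus fixed Weibull slope (3, a typical contrast-detection
value), logistic spread (8°, chosen so performance spans the 7 jitter
levels the way empirical curves do), and lapse 0 for both tasks. The
condition threshold follows from the facilitation definition:
α_offset = α₀ · 10^(−dB/20).

The packaged NT-like and ASD-like profiles encode the emulated study's
printed group statistics: baseline thresholds 0.035 ± 0.008 and
0.036 ± 0.007; jitter tolerances lines 47.83 ± 6.86 / 47.73 ± 8.28,
square 57.38 ± 6.01 / 51.93 ± 8.95; lines–square correlations 0.56 and
0.90; fixation rates 94.3% and 86.4%. Per-offset facilitation means are
only printed pooled over groups (4.41 / 3.34 / 2.57 / 1.76 dB) alongside
per-group overall means (3.56 and 2.41 dB), so the profiles use the
additive decomposition `pooled_offset + (group_overall − pooled_grand)` —
NT [4.95, 3.88, 3.11, 2.30], ASD [3.80, 2.73, 1.96, 1.15] — which
preserves both printed margins; the one printed per-group cell (offset
15°) departs slightly from additivity but the corresponding interaction
was not significant, so the additive profile is the defensible default.
The pooled per-offset SDs serve as the per-offset between-subject SDs.
The ASD windmill tolerance is synthetic (that shape was only tested on a
separate control group) and is set to the ASD lines value; a third
profile (`nt_three_shape`) encodes the separate group's three-shape
means. Gaze deviations are half-normal with scale set so that the
profile's fixation rate of draws falls within the 1.5° criterion —
enough structure to exercise the fixation filter, with no claim about
real eye-movement dynamics.

## Sessions and studies

An adaptive session is 300 trials: 60 aligned windows of 5 trials, each
window a random permutation of the five conditions (the strict reading of
"once every five trials"), each condition driven by an independent psi
state. A constant-stimuli session is 280 trials per shape: four blocks
of 70, ten presentations of each of the seven jitter levels per block,
shuffled within block. The target interval is drawn uniformly per trial,
independent of condition. Shape order is counterbalanced by participant
index (alternation for two shapes, Latin-square rotation for three).
Presentation durations and inter-stimulus intervals are recorded as
session metadata constants but not simulated — no analysis consumes
timing. Group studies derive per-participant generators from one seed
via `SeedSequence` spawn keys, so any participant's session is
reproducible in isolation.

## Statistics

Facilitation: `−20·log10(threshold/baseline)` per offset, per
participant. Mixed (group × within-factor) ANOVAs use classical
balanced-design sums of squares via pingouin, with partial
η² = SS_effect/(SS_effect + SS_error); the test suite verifies exact
agreement (≤ 1e−8) with an independent projection-style oracle, and the
df follow the balanced 2 × k layout (e.g., within df = (k−1, (k−1)(N−2))).
Post-hoc group comparisons per offset are independent-samples t-tests
with Bonferroni factor 4 (the per-offset family); all tests are
two-sided. The per-group lines–square Pearson correlations are compared
with Fisher's r-to-z: Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
Degenerate inputs (zero variance with zero difference) are flagged in the
report rather than dropped. The fixation filter retains trials with
deviation ≤ 1.5° *or* missing gaze (mirroring partially recorded
eye-tracking coverage) and reports per-participant exclusion fractions.

## Problem sizes in the test suite

The acceptance-level tests run the procedures at the scales the design
prescribes: psi recovery uses 200 replicates × 60 trials at three true
thresholds; jitter-tolerance recovery uses 300 replicates of the full
7 × 40 design across five true tolerances spanning the group means; the
face-validity check simulates 50 complete 13 + 13 studies (both tasks,
roughly 430,000 adaptive trials in total) and asserts only the
*direction* of the group facilitation effect and of the closure-benefit
interaction, since exact F/t/p values of the original human data are not
recoverable without the raw data.

## Known limitations

- Observers are stationary and exchangeable: no learning, fatigue,
  attention lapses beyond the fixed lapse parameter, or serial
  dependence.
- The between-subject hierarchy is the simplest consistent with reported
  means/SDs (normals with truncation); real parameter distributions may
  be skewed or correlated across tasks (only the within-task tolerance
  correlation is modelled).
- The windmill cell map is one plausible open-contour layout, not a
  reconstruction.
- Facilitation per offset is drawn independently per condition; any true
  participant-level coupling across offsets would change between-subject
  spread of the per-participant mean without changing group means.
- Luminance is normalized; nothing photometric can be concluded from the
  rendered images.
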