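# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `volmem`, and what the test suite does and does not
establish about real behavioural data.

## Task geometry

The task space is a cuboid enclosure. Training happens in a cubic baseline
environment of 3 m per side; memory is probed in the baseline and in four
deformed variants in which exactly one axis is multiplied by 1.33 (stretch)
or 0.67 (compression): HS/HC deform the horizontal x axis, VS/VC the
vertical z axis. Deformed axis lengths are derived from these factors
(3.99 m and 2.01 m). Coordinates are environment-local with the origin at a
fixed floor corner and z vertical; all environments share the origin
corner, which keeps the ground and two side walls invariant under
deformation (the wall-relative models are anchor-independent, so this
choice only fixes the coordinate bookkeeping). Wall naming: ground z = 0,
ceiling z = L_z, north y = 0, south y = L_y, east x = 0, west x = L_x.

Prediction fields live on regular grids of half-open bins: 25 bins per
axis in the baseline, and `round(25 × factor)` bins on a deformed axis
(round half up; 33 for stretch, 17 for compression), which preserves the
baseline bin size to within half a bin. Responses marginally outside the
walls (≤ 1 nm) clamp to the nearest bin; anything farther raises an error.

## Encoding models

Each model maps a 3D location to a feature vector; axes are ordered
vertical-first, and the fixed-ratio numerators are the distances to the
ground, north and east walls (equivalent to coordinate/axis-length). The
choice of reference wall per axis is immaterial for the dissimilarity —
opposing conventions are affine-equivalent — and is fixed only for
reproducibility.

* fixed-distance: (min(d_C, d_G), min(d_N, d_S), min(d_E, d_W)), metres;
* fixed-ratio: (z/L_z, y/L_y, x/L_x), dimensionless in [0, 1];
* boundary-proximity: 1/(d_w + c) for all six walls, c = 1.5 m (half the
  baseline axis; not fitted), components in (0, 1/c];
* ground-proximity: boundary-proximity without the ceiling component.

A target's feature vector is evaluated at its exact continuous coordinates
in the encoding environment (sharper than using its bin centre); test
feature vectors are evaluated at bin centres of the test environment. The
dissimilarity layer is the L² norm between the two, the similarity layer
S = max(D) − D with the max taken over that one target × test-environment
field, and the probability layer is the product of three per-axis softmaxes
with temperatures (T_x, T_y, T_z), computed in log-space with a per-axis
max shift. The per-axis product is **not** globally renormalised by
default: the product of per-axis conditionals does not generally sum to 1
over the volume, and the plain product is what enters the likelihood; a
`renormalize` flag provides the volume-normalised variant for sensitivity
checks. Response sampling in the synthetic generator necessarily uses the
normalised field.

## Temperature fitting and model comparison

Temperatures are fitted per participant and model by maximising the summed
log-likelihood of baseline test replacements, with L-BFGS-B on
log-temperatures (positivity by construction), box bounds [1e-3, 1e3],
finite-difference gradients, objective tolerance 1e-6, and a fixed
multi-start list (T = 1 plus five log-spaced starts at 10^{-2.5, -1.5,
-0.75, 0.5, 1.5}); the best final objective wins, so fits are deterministic
and exchangeable in trial order (trials are canonically sorted before
summation). Per-trial probabilities are floored at 1e-300 to avoid −inf.
Because the non-renormalised likelihood of a response bin involves only the
three similarity lines through that bin, the optimiser's objective reuses
precomputed lines and never rebuilds fields.

Fitted models are evaluated by summed log-likelihood on deformed-trial
sets, pooled within deformation plane (horizontal HS/HC vs vertical
VS/VC). Absolute fit is pseudo-R² = 1 − LL_model/LL_chance with chance the
uniform distribution over the test environment's bins. Cohort comparison
reports per-participant winners (exact ties reported as "tie") and
pairwise paired t-tests, Bonferroni-corrected over model pairs ×
conditions; single-participant inputs produce no group tests.

## Dispersion and anisotropy

Replacement precision is the per-axis median absolute deviation about the
median (MAD, metres, **without** the 1.4826 consistency constant — it is a
raw dispersion in metres, not a robust σ estimate), per participant ×
environment × target, requiring ≥ 2 responses. Horizontal MAD is the
arithmetic mean of the x and y MADs; vertical MAD is the z MAD. The
anisotropy index is AI = ln(MAD_V) − ln(MAD_H). Participant-level AI is
computed by median-centring responses per target and axis, pooling the
deviations across targets within participant × environment, and taking
per-axis MADs of the pool — every trial then informs one MAD, which is far
more stable than averaging six 5-trial MADs (a summary-table fallback that
averages per-target MADs exists for pre-aggregated input).
ΔAI subtracts the baseline AI from each deformed environment's AI and is
tested against the analytic expectations ln(V/H): VS +0.285, HC +0.400,
HS −0.285, VC −0.400 (one-sample t per condition × locomotion group,
Bonferroni-corrected for 8 comparisons).

One structural caveat the simulations make explicit: for *vertical*
deformations the expectation is exact for a deformation-tracking responder
(the vertical dimension is the single z axis), and simulated ratio-
preserving cohorts hit +0.285/−0.400 closely. For *horizontal*
deformations only one of the two averaged horizontal axes is deformed, so
a responder whose x-dispersion scales with the stretch shifts AI by
ln((1 + 1.33)/2) ≈ 0.15 rather than ln 1.33 ≈ 0.285. The ±0.285/0.400
horizontal expectations therefore describe full per-dimension scaling, and
simulated model-consistent cohorts systematically undershoot them; the
acceptance output reports the observed values as such. Two further
instrument effects bound how precisely simulated cohorts can hit the
analytic values: when the response spread approaches one grid bin, MAD is
quantisation-dominated and log-ratios become erratic, and when it
approaches the wall margins, truncation couples the axes (the feature
distance is a joint norm, so the per-axis softmax product is not
separable). The acceptance cohort uses a ratio-preserving responder at
T = 0.05 — spread comfortably between those regimes — and still shows
seed-to-seed wander of a few hundredths around the expectations.

Chance level simulates uniform random responses in the environment volume
(default 10,000 per target) and reports per-target means, the pooled mean
and a 2000-resample percentile bootstrap 95% CI (both pooled-then-averaged
and mean-of-target-means are returned; the bootstrap settings are a
package choice). For a central target in the baseline cube the mean error
converges to ≈ 1.441 m; margin-respecting target sets give pooled chance
levels in the 1.4–2.0 m band.

Distance–dispersion correlations are Spearman with average ranks; all-tied
inputs yield a missing value, excluded from group tests with a warning.
The boundary correlation relates per-target MADs to nearest-wall distances
(horizontal plane and vertical axis separately); the head correlation uses
|target height − head height| (default 1.74 m).

## Navigation metrics

State occupancy counts distinct visited bins of a 50×50×50 grid pooled
over a participant's trials. Path length is the cumulative frame-wise 3D
Euclidean distance. Path dissimilarity downsamples 40 Hz position streams
to 4 Hz by decimation (keep every 10th sample, first retained —
"downsampling" is read as decimation, not averaging), then computes DTW
with Euclidean local cost, no window, and the symmetric2 step pattern
(diagonal steps weighted twice — the default of the R `dtw` routine this
analysis stack is modelled on); cumulative distance is reported, with
per-step normalisation (÷(n+m)) and symmetric1 available as options.
Pairwise distances are averaged per target, then across targets. Heading
difference compares circular-mean azimuths (wrapped to [0°, 180°]) and
linear-mean elevations at placement between the feedback and test phases,
averaged over targets and the two components.

## Synthetic cohorts

The generator emulates the behavioural task conditions: six labelled targets
rejection-sampled ≥ 0.26 m from every wall and from each other, with
target D pinned at 1.65 m height (near head height); 6 familiarization +
6 learning + 48 feedback trials (8 per target) + 90 test trials in 5
blocks × 3 environments × 6 trials, environment order randomised within
block, every 6-trial set a permutation of the targets, no consecutive
target repeats, start points ≥ 1 m from the target. Stretch groups visit
baseline/HS/VS, compression groups baseline/HC/VC.

Responses are drawn from the generative profile's normalised probability
field and jittered uniformly within the sampled bin (avoiding artifactual
zero MADs at low temperature). Default profiles encode the locomotion
effects as generative ground truth: flying groups use boundary-proximity
with T = (0.020, 0.020, 0.045) — inflated vertical temperature, hence
vertical > horizontal dispersion; walking groups use ground-proximity with
T = (0.020, 0.020, 0.003). The walking vertical temperature is much
smaller because the ground-proximity similarity gradient along z is
shallow (a single ground term, no ceiling term), so equal temperatures
would produce *larger* vertical spread; 0.003 yields vertical < horizontal
MAD with baseline errors around 0.3 m, the precision regime of trained
participants. Default cohort size is 20 per group (configurable; tests and
the acceptance script use smaller cohorts, 6–13 per cell, sized to keep
runs in the minutes range).

Trajectories are 40 Hz piecewise-linear paths at 1 m/s from start through
waypoints to the response. Walking mode reuses one waypoint template per
target (plus 5 cm jitter) and clamps intermediate samples to a 0.5–1.9 m
head-height band, producing mutually similar, route-like paths; flying
mode inserts two fresh uniform waypoints per trial. Headings are the
instantaneous direction of travel. These trajectories are deliberately
schematic: they reproduce the *relative* structure the navigation metrics
measure (walking < flying path dissimilarity and occupancy) and carry no
biomechanical realism.

What passing tests show — and don't. The simulations verify internal
consistency: that the estimator recovers known temperatures (median
relative error < 20% at 600 trials over T ∈ {0.3, 1, 3}; higher
temperatures are weakly identified because the similarity range is
finite), that the generative model is identified from 90 trials per
simulated participant, and that MAD/ΔAI/correlation analyses recover the
structure built into the generator. They do not validate the models
against human behaviour, motor noise, lapses, or learning dynamics, none
of which the generator emulates.

## Determinism and degenerate inputs

Every stochastic operation takes a seed; cohort generation spawns
independent child streams per participant and stage, so outputs are
bit-reproducible per seed (the CLI `report` regenerates identically).
Degenerate cases are defined explicitly: constant dissimilarity gives a
flat similarity of zero (uniform softmax); zero-trial evaluations score 0;
AI is missing when either MAD is zero; all-tied correlations are missing;
exact model-likelihood ties are reported as ties.
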