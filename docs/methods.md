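# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the `vantage` pipeline: an analysis chain for viewpoint
trajectories recorded while people inspect a 3D artwork through an orbit
camera on a flat screen.

## Data model and preprocessing

A trajectory log is a per-participant TSV stream of timestamped camera and
look-at-target coordinates (columns `t_ms, cam_x, cam_y, cam_z, tgt_x,
tgt_y, tgt_z, phase`; the recording format names TSV but not a column
layout, so this schema is the package's convention). Coordinates are
right-handed, y-up scene units; the stimulus faces +z and the camera
starts in front of it. Timestamps are integer milliseconds at
browser-frame granularity (at most 60 records/s); duplicate timestamps
collapse to the last row, and rows with unparseable or non-finite values
are dropped and counted, with parsing failing outright above a 1% bad-row
fraction.

Three participant-level exclusions mirror the study protocol: a camera
taken too far from the target at any point during the main trial, an
extremely short total travel, and a mean logging rate below 10 records/s.
The protocol states the criteria but not the first two cutoffs; the
defaults express them relative to each participant's initial
camera–target distance (10x for "too far", 1% for "too short"), and both
are configuration keys. A participant matching any criterion is removed;
reports carry per-criterion counts alongside the overlap-adjusted union.

A *fixation* is a maximal run of frames whose successive camera
displacements are all at most `eps` (default 0 — an orbit camera moves
only under user input, so logged coordinates repeat exactly during a
hold) and whose duration, last minus first frame time, is at least 500
ms. Each fixation contributes a single signed view-angle theta: the
azimuth of the run-mean camera about the run-mean target's vertical axis,
measured from the front (+z) and wrapped to (-pi, pi]. Elevation is
deliberately discarded: theta is treated as a univariate circular
outcome. Dwell times are retained and can optionally weight the
likelihood (weights normalised to the event count); the default is
unweighted.

## Movement statistics and the classical layer

`d_total` is the natural log (base configurable) of the summed Euclidean
distance between temporally adjacent camera positions in the main trial;
`d_cov` is the same statistic on the practice phase and enters as an
ANCOVA covariate to absorb general movement tendency. The ANCOVA uses
partial (Type-III-style) sums of squares — appropriate for the unequal
group sizes — with error df N − k − 1. The nine Likert dimensions are
tested jointly with Pillai's trace, T = sum lambda/(1+lambda) over the
eigenvalues of E⁻¹H, with the standard F approximation (s = min(p, k−1),
m = (|p−k+1|−1)/2, n' = (N−k−p−1)/2, dfs s(2m+s+1) and s(2n'+s+1)); with
p = 1 this reduces exactly to one-way ANOVA, which the tests verify.
Pairwise follow-ups re-test two-group subsets with Bonferroni-adjusted
p-values. Effect sizes are partial eta squared with confidence bounds by
noncentral-F inversion; the bounds are 90% two-sided (the conventional
companion of a 5% F test — the reporting convention for such intervals
varies, so the level is a parameter) and are computed lazily because the
inversion costs far more than the test itself.

## The hierarchical von Mises model

Fixation angles follow, per participant i with condition c_i in
{narrative = 0, process = 1, creator = 2}:

    theta_ij ~ VonMises(mu_i, kappa_i)
    mu_i     ~ Normal(alpha_mu(c_i), sigma_mu)
    kappa_i  ~ Normal(alpha_kappa(c_i), sigma_kappa) truncated to >= 0
    alpha(c) = alpha^n + delta^np [c = 1] + delta^nc [c = 2]

The null model H0 fixes all four deltas at zero; H1 leaves them free.
Condition effects act only on the group means; the spreads are shared.
The kappa hierarchy is a truncated normal on the natural concentration
scale (an identity link; a fitted reference concentration near 1.7 is
consistent with that scale), with the truncation normaliser
Phi(alpha_kappa(c)/sigma_kappa) included since it depends on parameters.
The mu hierarchy lives on the real line without wrapping, which is valid
when fixations concentrate near the front (angles near 0) — the regime
an orbit camera and a front-facing artwork produce. For diffuse angle
data this linearisation is a documented limitation.

The likelihood depends on the data only through per-participant
sufficient statistics (sum cos theta, sum sin theta, n), so fitting cost
is independent of the fixation count.

### Priors

Group-level priors are weakly informative and echoed into every result
file, because Bayes factors are meaningless without them:

* alpha_mu ~ Normal(0, 1) (radians),
* alpha_kappa ~ Normal(0, 5) truncated to >= 0,
* sigma_mu, sigma_kappa ~ half-Normal(0, 2),
* each delta ~ Student-t(df = 1, 0, 0.3), i.e. Cauchy(0, 0.3), with
  `delta_df <= 0` selecting a Normal(0, `delta_scale`) instead.

The heavy-tailed scaled prior on the condition effects is the standard
family for Bayes-factor tests of effects: it concentrates mass at
plausibly small shifts while its tails do not punish a genuinely large
one. This choice matters. In simulation at the fitted group means —
where only the process-condition concentration shift (-0.466) is
materially non-zero — a light-tailed Normal(0, 1) prior on all four
deltas makes the Occam penalty of the three null effects cancel the one
real effect, pinning log BF10 near zero; the Cauchy(0, 0.3) default
yields clearly positive evidence on effect-truth cohorts and clearly
negative evidence on null cohorts, the qualitative behaviour the model
comparison exists to detect.

### Sampling

No general-purpose MCMC engine in the dependency set fits this model, so
the sampler is part of the package: adaptive Metropolis-within-Gibbs on
the unconstrained scale (log transforms with Jacobians for kappa_i,
alpha_kappa, and the sigmas), compiled with numba. Each iteration runs

1. a joint random-walk proposal of (mu_i, log kappa_i) per participant —
   participants are conditionally independent given group parameters, so
   each accepts independently;
2. sequential scalar proposals for every group parameter;
3. hierarchical *translation* moves, which shift a group location
   together with its participants' parameters (for the kappa block the
   translation acts on the constrained scale, with the z-space Jacobian
   correction in the acceptance ratio), and *scale* moves, which multiply
   a sigma and its participants' residuals jointly (a deterministic
   scaling map whose log-determinant enters the ratio).

The translation and scale moves decorrelate the funnel-shaped
group/participant geometry that defeats plain coordinate-wise
random-walk updates; without them the concentration spread mixes an
order of magnitude slower. Proposal scales adapt by Robbins–Monro toward
acceptance targets of 0.35 (2-D participant block) and 0.44 (scalar
moves) during warmup only. Defaults are 4 chains of 1000 warmup plus
1000 retained iterations; the heavier simulation studies use 1500+1500.
Convergence is gated on rank-normalised split-R-hat (maximum of the bulk
and tail-folded statistics, cross-checked against arviz) over every
parameter, threshold 1.05 by default; failure flags the result rather
than raising. Identical seeds and configuration reproduce identical
draws.

Simulation-based calibration at reduced scale (group parameters drawn
from their priors, tiny cohorts refitted 100 times) verifies that the
rank of the generating group mean within thinned posterior draws is
uniform.

## Marginal likelihoods and the Bayes factor

Model evidence is estimated by the iterative optimal-bridge scheme with
a moment-matched multivariate-normal proposal fitted to the first half
of each chain and evaluated on the second half; covariance is shrunk 5%
toward its diagonal (shrinkage affects efficiency, never validity). The
fixed-point iteration is run in a guarded algebraic form in which
extreme log ratios underflow to zero instead of overflowing, and an
independence-approximation relative Monte-Carlo error accompanies every
estimate. On a conjugate normal–normal toy the estimator matches the
closed-form evidence to well under 0.01 nats.

For the hierarchy itself the bridge operates on the *group-level
marginal posterior*: the participant parameters are integrated out
numerically, per participant and group point, by adaptive Gauss–Hermite
quadrature (inner mu integral centred by damped Newton on its Laplace
point, 16 nodes; outer kappa integral in log-kappa with a coarse-grid
mode search, parabola refinement, and 24 nodes; node windows widened by
a factor 1.6). The evidence of the marginal equals the evidence of the
full hierarchy, but the bridge proposal then lives in 4 or 8 dimensions,
where a Gaussian overlaps the posterior well — a full-dimensional bridge
over several hundred correlated participant parameters is numerically
hopeless with random-walk draws. Quadrature accuracy was validated
against `scipy.integrate.dblquad` (about 1e-5 nats per participant at
realistic fixation counts, at worst about 1e-3 for single-fixation
participants) and the whole marginal-plus-bridge chain against
brute-force prior Monte-Carlo on a tiny hierarchy. The compiled kernel
is pinned to its numpy reference implementation by a unit test.

BF10 = exp(logml_H1 − logml_H0), with the H0 marginal always computed
from its own constrained refit, never by conditioning H1 draws. Because
a single estimate inherits noise from both the draws and the proposal,
the stability analysis refits both models from fresh seeds (MCMC and
bridge seeds both vary) n times — 10 by default — and reports every
repetition with its min/max envelope; repetitions failing the R-hat gate
are excluded and counted.

## Synthetic cohorts

The simulator generates top-down through the same hierarchy: defaults
are the study's conditions — group sizes 108/110/99 and group-level
parameters at the fitted condition-effects posterior means (reference
concentration 1.724, process shift −0.466, mean direction 0.344, spreads
0.385/0.820). Dwell times are log-normal (median 900 ms, 0.6 log-units)
and fixation counts negative-binomial (mean 30, shape 10): the source
data report neither distribution, so these are package choices, fixed
once and recorded in every ground-truth sidecar. Planned fixations are
rendered into orbit-camera trajectories — bit-exact position repeats
during each dwell, constant-angular-speed shortest-arc transits with
linear radius interpolation between them — sampled at a nominal rate
(60 Hz default) with optional random frame drops to exercise the
logging-rate exclusion. The frame grid snaps the frame following each
segment boundary onto the boundary, so every hold starts exactly on a
logged frame and detection inverts the plan (angles to 1e-9, dwell
within one frame interval) while the record rate stays at the nominal
cap. Schedules that exceed the 100-second trial are rescaled with a
warning, and the final hold is padded to the trial end.

Practice-phase movement is generated with correlation 0.4 to main-phase
movement through a shared latent, making the ANCOVA covariate
meaningful. Likert vectors are drawn per condition with small additive
shifts in the direction of the study's findings (process raises empathy
and imagination; creator raises empathy and interest) over a
compound-symmetric covariance — enough structure for MANOVA smoke tests,
not a calibrated psychometric model. A separate constructor builds
cohorts in which the three exclusion criteria flag exact counts with
controlled overlap, for the worked example (3/17/37 flags, one double
flag, 56 excluded of 317).

What the simulator does not emulate: genuine eye movements (the
camera–target line stands in for gaze), target shifts during a session,
serial dependence between successive fixation angles, elevation
preferences, and any cognitive model of why conditions differ. Passing
recovery tests therefore show that the inference machinery is correct
under the model's own assumptions, not that the model is adequate for
any particular real dataset.

## Dwell-surface mapping

Viewing time is projected onto the stimulus by casting each frame's
camera-to-target line against the mesh; this proxy is exact for an orbit
camera's optical axis but approximate as gaze. Intersection uses a
vectorised Möller–Trumbore first-hit test over all faces (no broad
phase; validated against an analytic sphere to 1% on an icosphere).
Hits accumulate the frame's duration into a voxel grid over the mesh
bounding box (default edge 1/32 of the largest extent, padded half a
voxel), per condition; per-condition proportions over occupied voxels
(p_n, p_p, p_c) normalise to 1. A voxel's color divides the proportions
by their maximum onto (green, red, blue) for (narrative, process,
creator); voxels whose minimum channel exceeds 1 − 0.15 are dropped as
near-white. The cube size and whiteness threshold are not documented by
the source visualisation, so both are configuration keys.

## Problem sizes in the shipped studies

The canned validation studies run at sizes chosen to finish on one core
in minutes: parameter recovery and null centering use 20 replicates at
half the study's group sizes (54/55/50) with ~30 fixations per
participant; the evidence-direction study uses 5 refit repetitions per
truth at 90 participants per condition with 1500+1500 MCMC iterations
and bridges thinned to ~2000 density evaluations. The exclusion worked
example runs at the full 317; the degrees-of-freedom checks are exact at
the study's design sizes.

## Known limitations

* The unwrapped mu hierarchy biases group means if fixations are diffuse
  or concentrate near ±pi.
* The identity-link kappa hierarchy permits condition means near zero
  only through the truncation; a log-link variant would be the natural
  extension for low-concentration regimes.
* Bayes factors are prior-sensitive by nature; results are only
  comparable under the echoed `PriorSpec`.
* The stationarity rule (`eps = 0`) assumes noiseless logged coordinates;
  real logs with interpolation jitter need a positive `eps`.
* Within-session serial structure of fixations is ignored, as is the
  repeated second viewing trial of the original procedure.
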