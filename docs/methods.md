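# Methods

This package implements a Bayesian reanalysis pipeline for a
two-arm rehabilitation study in chronic spinal cord injury (SCI):
15 participants received two weeks of passive motor rehabilitation
(exoskeleton-assisted walking or passive mobilisation), with one arm
additionally performing motor-imagery (MI) training.  Peripersonal
space (PPS) around the feet and the mental representation of body
parts were probed at baseline (T0), post-training (T1) and one-month
follow-up (T2) with two reaction-time paradigms:

* **LLCCT** (Lower Limbs Crossmodal Congruency Task): vibrotactile
  targets at the top/bottom of handheld stimulators, visual LED
  distractors near the feet.  The congruency cost (incongruent minus
  congruent RT) is larger when the distractor is on the same body side
  as the touch (homolateral) *if* the space near the feet is
  represented as peripersonal; the homolateral-minus-bilateral
  difference of congruency effects therefore indexes PPS.  Blocks of
  162 trials (128 factorial test trials, 18 catch, 16 false
  stimulations) are run with the feet in the apparatus (REAL) and
  hidden (VOID, a spatial control).
* **BST** (Body Sidedness Task): a Simon-like task in which a red/blue
  circle is superimposed on a left/right hand or foot photograph; the
  congruency effect of the task-irrelevant body side indexes the
  body-part representation.  Sessions have 4 background blocks x 24
  trials, responses within 1 s.

## The hierarchical ex-Gaussian congruency model

The centrepiece estimates Congruency Effects (CEs) directly from raw
trial RTs rather than from participant-level difference scores.  For
trial *i* of participant *p(i)*:

    rt_i ~ ExGaussian(mu_i, sigma, tau)
    mu_i = b0 + a_p(i) + c_i * CE_i
    CE_i = x_i' beta + z_i' u_p(i)

* `c_i` is 1 on incongruent, 0 on congruent trials — deliberately not
  mean-centred, so CE is exactly the incongruent-minus-congruent shift.
* `x_i` holds the 12 population-level terms: intercept, Space (or
  Background for the BST), Group, linear and quadratic Time, and all
  their interactions.  Two-level factors use sum-to-zero (+/-1/2)
  codes (homolateral, hand, and Motor+MI are the positive levels);
  Time uses orthogonal polynomial contrasts (-1, 0, 1) and (1, -2, 1).
* `z_i` holds the participant-level (group-level) terms: a varying CE
  intercept, the two time contrasts, and Space (Background for BST).
  `a_p` is a varying RT-baseline intercept.
* Priors: every population effect beta (and b0) is Normal(0, variance
  5).  Because the model runs in **seconds**, this is weakly
  informative on the effect scale (prior SD 2.24 s vs effects of tens
  of ms); on a millisecond scale the same prior would be absurdly
  tight.  Reports convert to ms at render time only.
* Participant effects: `a_p ~ Normal(0, sd_a)` (centred — each baseline
  is pinned by hundreds of trials); CE effects are non-centred
  (`u = sd_u * z`, `z ~ Normal(0,1)`) because they are prior-dominated.
  All scale parameters (sd_a, the four sd_u, sigma, tau) get
  half-normal(1 s) priors on positive support.
* sigma and tau are shared across trials and participants (a
  per-participant option was considered and rejected as the default:
  with ~380 trials per participant the shared fit is stable and the
  fitted tables report only population terms).
* REAL and VOID are fitted separately and never share rows; the BST
  model is the same structure with Background in place of Space.

Trials without a usable RT — catch and false-stimulation trials,
response errors, BST timeouts (>1 s) — are excluded before fitting.

### Sampling

No general-purpose MCMC framework is assumed: the engine
(`ppsbayes.sampler`) is a blocked kernel purpose-built for this model
family, with all chains (4 by default) updated simultaneously through
vectorised log-posterior evaluations:

* a **Hamiltonian block** for the mean structure and log-scale
  hyperparameters `[b0, beta, log sd_a, log sd_u, a, z]` with analytic
  gradients (the ex-Gaussian score uses the inverse-Mills ratio
  computed in log space); diagonal mass matrix and per-chain step size
  adapted during warm-up (target acceptance 0.8, ~12 leapfrog steps);
* random-walk Metropolis blocks with adapted covariance for
  (log sigma, log tau) and the hyper-scales;
* structured Metropolis moves for the directions random-walk and even
  plain HMC traverse slowly: a translation move (b0 up, all a_p down),
  "ridge" moves that shift one population effect and compensate the
  participant effects (likelihood-invariant; the state-dependent
  proposal is symmetric because the scales it uses are outside the
  updated block), and Jacobian-corrected scaling moves through each
  variance funnel (sd up, effects rescaled).

Warm-up adaptation (step sizes, proposal covariances, mass matrix) is
frozen afterwards, so retained draws come from a fixed kernel.
Initialisation uses method-of-moments ex-Gaussian estimates and
per-participant mean RTs, with overdispersed jitter across chains.

Every reported effect is gated on split-chain Gelman-Rubin R-hat < 1.1
and autocorrelation-corrected effective draws n_eff > 10 (Geyer initial
monotone sequence estimator), plus a model-level posterior-predictive
p-value (default discrepancy: grand mean RT; a variance discrepancy is
available) that should land near 0.5.  Known limitation: the
variance-component posteriors themselves (sd_u) mix slowly when the
data barely identify them (R-hat up to ~1.5 on some runs); they are
nuisance parameters here, are not part of the reported effect tables,
and the population-effect chains meet the gates regardless — but sd_u
point estimates should not be quoted from a single default run.

## Decision outputs

* **Savage-Dickey Bayes factors.** BF10 = prior density at 0 divided by
  posterior density at 0.  The posterior density is estimated from the
  draws by an exponential-family fit: log-density modelled as a
  polynomial on the standardised scale, coefficients by maximum
  likelihood (closed-form gradients, BFGS, normalisation by quadrature
  on a finite window), degree chosen by BIC among {2, 3, 4}.  Degree 2
  is exactly a Gaussian fit, so effectively-normal posteriors
  extrapolate correct Gaussian tails to nulls far outside the draws —
  the regime where kernel estimates collapse.  Numeric BFs are
  returned raw; tabled output caps the display at ">150".
  Thresholds: BF10 > 5 supports the effect (H1), < 1/5 the null (H0),
  otherwise inconclusive.  An irreducible caveat: when the null sits
  ~9 posterior SDs out, any draw-based estimate of log BF carries
  Monte-Carlo spread of order 0.5 at 10^4 draws (the CRLB on the
  fitted variance term); accuracy checks there average over draw sets.
* **Mode and 95% HDI.**  The mode is the argmax of the same smooth
  density fit (restricted to the draw range, so boundary-peaked
  densities report the boundary); the HDI is the shortest contiguous
  interval containing 95% of sorted draws.  Reports use the
  `mode {low, high}` format.
* **Marginal cells.**  Cell posteriors are per-draw linear combinations
  of the population-effect draws via the contrast matrix; the PPS test
  is the homolateral-minus-bilateral contrast per (group, timepoint),
  the BST test each background's cell against zero.  Decisions use
  Pr(x > 0) >= 83.5% / <= 16.5% (5:1 posterior odds, matching the BF
  thresholds); an all-zero contrast reports 50% by convention.

## Clinical-scale models

Ordinal scales (PSFS spasm frequency/intensity, Modified Ashworth,
MRC strength, VMIQ-2 imagery vividness, NLI rank) use cumulative-logit
regression with strictly increasing free thresholds (first threshold
plus log-spacings) and Normal(0, 5) effect priors; the logit link is
the documented default (the probit alternative was not pursued).  MRC
enters as one ordinal summary per participant/timepoint — the worst
movement score — since only a single scale summary is reported per
group.  Age and lesion onset use a robust Student-t linear model
(nu - 1 ~ Exponential(mean 29), residual scale half-normal).  The
linear-model coefficient block samples in whitened coordinates
preconditioned by the approximate Gaussian posterior covariance
`(X'X/s0^2 + I/5)^(-1)` with Hamiltonian updates: near-collinear
small-n designs (the 12-term covariate model on 15 participants) mix
prior-dominated directions of SD ~2.2 with data-pinned directions
three orders of magnitude tighter, a spread neither a random walk nor
a diagonal mass matrix covers.

The T1 covariate models regress each participant's post-training CE
(REAL homolateral trials for LLCCT; foot-background trials for BST) on
Group, five z-scored covariates — NLI rank (rostral-to-caudal integer
C1..L5 -> 1..25), lesion onset, PSFS frequency and intensity, VMIQ-2
average — and the five Group x covariate interactions (12 terms,
Student-t likelihood).  z-scores use the n-1 sample SD.

## The synthetic study

The generators are first-class, tested code and define the study
conditions; no download is needed.

* **Cohort**: the published 15-row demographics table ships verbatim as
  a fixture (8 Motor / 7 Motor+MI, chronic adult-onset lesions C5-L1,
  >= 8 rehabilitation sessions); clinical-scale scores, which the
  demographics table does not print, are drawn from realistic
  categorical distributions (mostly AIS-A, low-to-moderate spasm
  scores).  A fully synthetic cohort generator with the same structure
  is available for arbitrary sizes.  Note the published summary row
  (mean age 51.22) reflects the pre-exclusion sample of 16 and does
  not equal the mean of the 15 rows; descriptives here are computed
  from the rows, matching the printed lesion-onset statistics
  (21.22, population SD 9.81).
* **Designs**: exact trial counts (162-trial LLCCT blocks as
  8 repeats x 16 factorial cells + 18 catch + 16 false stimulations —
  the printed total constrains the sum, the decomposition is
  configurable; 96-trial BST sessions in the two counterbalanced
  block orders; 24-item MI training sessions; the 250 ms tactile
  profile with 30 ms visual lead).
* **RTs** are drawn from the model's own generative process.  Residuals
  `ExGaussian(mu 0.42, sigma 0.035, tau 0.050)` give a mean simple RT
  of 0.47 s with trial SD ~61 ms, calibrated so that posterior cell
  uncertainties (~3-5 ms) match the precision of the study's reported
  cell summaries; participant SDs are 40 ms (baseline) and 8/3/3/4 ms
  (CE intercept/time/time^2/space).  2% of test trials are response
  errors (the study does not report its error or exclusion rates; the
  value is configurable and carries no analysis weight since errored
  trials are simply dropped).  BST responses beyond 1 s time out.
* **Ground truth** (`default_truth`): the REAL condition carries a PPS
  signature only in Motor+MI at T1 (homolateral 40 ms vs bilateral
  10 ms); every other cell's gap is 4 ms or less, with magnitudes
  loosely following the reported cell modes; VOID has no
  homolateral/bilateral differences (it is the control condition);
  the BST truth mimics the delayed foot-representation recovery at T2.
  `null_truth` sets every cell to zero for calibration runs.

What passing recovery tests do and do not show: the simulator
implements exactly the fitted model's generative process (shared
sigma/tau, Gaussian varying effects, ignorable exclusions), so
recovery demonstrates correctness of estimation and decision
machinery, not robustness to real-data violations (RT drift,
sequential effects, non-ex-Gaussian contamination, informative
missingness).  Two stochastic facts about the study scale are worth
keeping in mind when reading single runs: (i) with 15 participants the
realised group means of the varying effects are part of what the data
identify, so recovery is assessed against the cohort-realised cell
values (population effect + realised group-mean deviations); (ii) the
83.5% decision threshold is a ~1 SD criterion, so a no-effect cell has
a nontrivial (~5-15%, depending on the true gap) chance of crossing it
in any one simulated study — the same order of false-positive risk the
design itself carries.

## Problem sizes and defaults

Default MCMC: 4 chains, 2,000 iterations, 1,000 warm-up.  The
full-design recovery runs reported by `scripts/acceptance.py` and the
acceptance tests use 4,000 iterations (1,500 warm-up) on the complete
15-participant REAL dataset (~5,700 answered trials); null-calibration
replicates use 2 factorial repeats per cell (~1,400 trials) and 1,500
iterations, sizes chosen to give comfortable convergence margins at
desk scale.  Clinical and covariate models are small (n <= 200) and
run in under a second each.
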