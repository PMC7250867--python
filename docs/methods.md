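# Methods

This note documents the models, algorithms and design choices behind
`postbias`: what is simulated, how each statistic is computed, which
conventions were fixed where several were defensible, and what the
synthetic-data tests do and do not establish about real recordings.

## The task being emulated

The synthetic generator (`postbias.synth`) emulates a two-stage random-dot
motion task with a positive-evidence (PE) manipulation. Dots move
coherently in *both* directions: the incorrect-direction coherence is fixed
at 5% (low PE) or 15% (high PE) and the correct-direction coherence is
staircased per condition to a common target accuracy (71% by default).
Because accuracy is matched while total motion energy differs, high-PE
stimuli raise confidence without raising accuracy — which is what lets the
analysis attribute downstream effects to confidence itself.

Each trial: initial left/right decision with a confidence rating (7-point
scale on [0.5, 1], or a binary high/low split in the MEG-style variant), a
post-decision evidence sample always in the true direction (weak, or
strong = weak x 1.3; incorrect-direction coherence equal to the mean of the
two staircased incorrect values; weak correct coherence equal to the mean
of the two staircased correct values), then a final decision. Sessions are
balanced 2 (PE) x 2 (post-decision strength) factorials, 90 trials per cell
by default. Confidence reports are rewarded with the proper quadratic
scoring rule `100 * [1 - (correct - confidence)^2]`.

### Generative observer

* **Psychometric function.** P(correct) is logistic in net coherence
  (correct minus incorrect) with slope 18 per unit coherence. The
  pre-decision stage is a symmetric diffusion whose drift is chosen as
  `v = slope * net_coherence / a`, which makes the diffusion's accuracy
  from an unbiased start equal the psychometric function exactly
  (P = expit(v*a) at z = 1/2, s = 1). Staircase calibration therefore
  transfers exactly to the diffusion stage.
* **Staircase.** A transformed weighted up/down rule: coherence rises by
  `step_up` after an error and falls by `step_up * (1-p)/p` after a correct
  response, whose equilibrium is exactly the target accuracy p. Step sizes
  are configurable; runs that cannot reach the target anywhere in the
  achievable range, or that spend much of their tail pinned at a range
  limit, are flagged as non-converged rather than returned silently. Both
  PE conditions start from the same net coherence (incorrect + 0.10) so
  they approach equilibrium symmetrically.
* **Confidence.** A logistic function of accumulated pre-decision evidence
  — operationalised as the signed terminal bound plus (log) decision speed
  — plus an additive positive-evidence offset and Gaussian report noise,
  mapped into [0.5, 1] and snapped to the 7-point scale. The offset
  produces the "confidence up, accuracy flat" signature; its default (0.6
  on the latent scale, roughly +0.06 mean confidence) was chosen to give a
  clearly detectable but not saturating condition difference.
* **Post-decision stage.** An accuracy-coded diffusion (upper bound =
  correct) whose drift tracks the post-decision net coherence and whose
  starting point (logit scale) and drift additionally depend on scaled
  confidence (c in [-1,1]), the initial decision (d = +1 correct /
  confirmatory, -1 error / disconfirmatory) and their product. The default
  ground truth (z: 0.25 d + 0.15 c*d; v: 0.40 d + 0.45 c*d) makes
  high-confidence errors "sticky": changes of mind become rarer after
  high-confidence initial decisions, conditional on an initial error.

### Sensor epochs

Epochs are trials x channels x samples (273 x 821 at 100 Hz by default,
covering -200..8000 ms). One fixed unit-norm spatial pattern carries a
signed amplitude: a ramp during the pre-decision window signed by the
initial choice (+ right, - left), and during the post-decision window a
linear trajectory with a per-trial intercept (signed by the initial choice
— the continuation of the initial decision) and slope (signed by the
presented direction). Unsigned slopes depend on the condition codes plus
trial-level Gaussian jitter (sd 0.1). Noise is Gaussian, white in time,
with exponential spatial correlation across channels (length 10 channels
by default) — enough structure to make whole-sensor decoding nontrivial
while keeping generation cheap. The default noise scale (0.5 per channel
against a unit-norm pattern) puts single-timepoint decodability well below
ceiling while the full chain recovers trial slopes at r ≈ 0.9.

What the generator does *not* emulate: 1/f spectra, artifacts, sensor
drift, non-stationary patterns, or any nonlinear relation between the
latent decision variable and the sensors. Passing recovery tests therefore
demonstrates the correctness of the analysis pipeline under its own
assumptions, not robustness to the physiology of real MEG.

## Wiener first-passage core (`postbias.ddm`)

The defective first-passage density uses the standard small-time /
large-time series split in normalised time u = t/a^2, with the truncation
index chosen per evaluation from the usual error bounds at tolerance 1e-7;
whichever series needs fewer terms is used. The diffusion scale is fixed
at s = 1 (all parameters are relative to it). Accuracy coding throughout:
the upper bound is the correct response; the upper-bound density is the
lower-bound density under (v, z) -> (-v, 1-z). The analytic absorption
probability `(1 - e^{-2vaz}) / (1 - e^{-2va})` and an Euler–Maruyama
simulator serve as cross-checks in the tests.

### Regression model family

Ten models share subject-level base parameters (drift intercept,
starting-point intercept on the logit scale, boundary intercept on the log
scale, log non-decision time), each drawn from a group normal
distribution. Covariate effects are group-level fixed effects. Drift
always carries post-decision evidence strength (coded -1 weak / +1
strong); boundary separation always carries confidence. Model 1 adds
nothing else; models 2–4 add confidence to z, v, or both; 5–7 the initial
decision; 8–10 the interaction together with both main effects (the
printed full model contains the main effects, and the hierarchy principle
argues against pure-interaction models). Confidence ratings are mapped
affinely from [0.5, 1] to [-1, 1]; the binary MEG-style rating maps to
{-1, +1}.

Links: identity for drift, logistic for the starting point (keeps
z in (0,1)), exponential for boundary separation (keeps a > 0). Boundary
uses the parametric confidence covariate (the binary/parametric choice is
not determined by the reporting convention; parametric is assumed and
noted here).

### Likelihood and fitting

Trials with final RT < 200 ms are discarded before fitting. The trial
likelihood is a mixture: with probability 0.95 the Wiener density at the
observed bound, with probability 0.05 a contaminant uniform over the
observed RT range and both responses.

The sampler is an adaptive Metropolis-within-Gibbs scheme written for this
package (no general-purpose hierarchical DDM sampler is available in the
dependency set):

1. each subject-parameter kind is updated for all subjects in one block
   (subject likelihoods are independent given the group, so acceptance is
   per subject from one vectorised likelihood pass);
2. each fixed-effect coefficient gets a scalar random-walk update against
   the full-data likelihood;
3. group means are conjugate normal Gibbs draws; group variances are
   conjugate inverse-gamma draws (prior IG(2, 0.125), i.e. a weakly
   informative prior with sd around 0.35 — a random-walk update here mixes
   poorly when the true spread is small);
4. proposal scales adapt toward ~0.35/0.40 acceptance during burn-in only,
   preserving detailed balance afterwards.

Priors on fixed effects are N(0, 2^2); subject-level group-mean priors are
broad normals centred on typical values (log a near log 1.5, log t0 near
log 0.3). Chains are seeded deterministically from the fit seed; rerunning
with the same configuration reproduces draws bitwise.

Default desk-scale settings are 4 chains x 3000 sweeps with 1000 burn-in
and no thinning; the original-scale settings (100,000 sweeps, 50,000
burn-in, thinning 25) remain reachable through the configuration. Note the
printed description of that schedule is internally inconsistent (50,000
retained / 25 = 2,000, not 2,500); the implementation always reports the
actual retained count.

Convergence is monitored with the classic Gelman–Rubin potential scale
reduction factor (floored at 1; values below 1 are finite-sample
artifacts); any group-level R-hat above 1.1 flags the fit as
non-converged. Model comparison uses DIC = mean deviance + pD with
pD = mean deviance - deviance at the posterior mean.

Recovery, at 20 subjects x 400 trials with coefficient magnitudes >= 0.3
and reduced MCMC (2 chains x 1200 sweeps), returns all starting-point and
drift coefficients within +/-0.15 of truth; DIC selects the generating
model in the model-selection simulations. Problem sizes in the tests
(5–20 subjects, 120–400 trials, hundreds to ~1200 sweeps) were chosen as
the smallest at which these guarantees hold comfortably.

## Neural decision variable (`postbias.neural`)

Preprocessing: polyphase resampling 600 -> 100 Hz (an 8200 ms segment of
4921 samples becomes 821 samples) and a 4th-order zero-phase Butterworth
high-pass at 0.5 Hz. Features are 100 ms boxcar means stepped every 10 ms;
windows are right-aligned to the nominal timepoint (the half-open interval
(t-100, t]) and clipped at epoch edges.

Per-timepoint linear SVMs (regularization constant C = 1) are trained on
the pre-decision phase to predict the initial choice, with features
z-scored per channel across training trials only. The decision variable is
the *geometric* signed distance to the hyperplane — weights are normalised
to unit norm — applied at the corresponding post-decision timepoint. Two
conventions matter here and were fixed deliberately:

* **Unit-norm weights.** The raw SVM decision value carries the margin
  scale, which varies across training timepoints; dividing by ||w|| makes
  the DV comparable across timepoints, which a within-trial *slope*
  requires.
* **Pooled post-phase normalization.** Post-phase features are normalised
  per channel with statistics pooled over the analysis window (estimated
  on training trials only). Per-timepoint scaling would give every
  timepoint its own unit and distort within-trial trends; pooling keeps
  the DV timeseries in a single unit system while still removing channel
  scale. In the realistic low-SNR regime the two conventions nearly
  coincide (the across-trial SD is noise-dominated and flat in time); they
  differ only in the high-SNR synthetic regime used for recovery testing.

DV extraction uses the leave-one-out protocol: the rules (and all
normalization statistics) used to score a trial are estimated without that
trial. A per-trial straight line over the window from post-stimulus onset
to the peak-decodability timepoint gives the intercept (starting-point
analogue) and slope (drift analogue); flipping the sign on leftward-motion
trials yields unsigned summaries. Peak decodability is the maximum of the
group-average diagonal of the temporal generalization matrix, ties broken
toward the earlier timepoint; per-subject peaks are available by running
per subject.

Temporal generalization trains at every pre-decision timepoint and tests
at every post-decision timepoint, under stratified 4-fold cross-validation
repeated 100 times (both reduced in the bundled pipeline configuration).
Strata are choice x confidence x change-of-mind combinations; where a
combination holds fewer trials than folds (common at reduced session
lengths, since high-confidence changes of mind are intrinsically rare) the
pipeline falls back to choice x confidence strata and records a warning.
AUC (rank-based, over the continuous DV) is reported over all trials and
within the four confidence x change-of-mind cells. Sensor contributions
average held-out subset-decoder accuracy (stratified 4-fold) over random
30-sensor subsets, 2500 repetitions at full scale, crediting each subset's
accuracy to its members.

## Group statistics (`postbias.stats`)

* **Hierarchical regression.** Linear mixed models (REML, statsmodels
  MixedLM) with subject random intercepts; logistic outcomes use the
  variational Bayes binomial mixed GLM with Wald z tests. Degrees of
  freedom for t statistics are residual-based (n - p), matching the
  t(thousands) reporting convention rather than Satterthwaite. A
  derivative-free refit handles the degenerate zero-group-variance corner.
* **Mediation.** Positive evidence (coded LPE = 1, HPE = 2) -> confidence
  -> change of mind (0/1), controlling for accuracy, RT, post-decision
  strength and accuracy x strength. Within each subject, path a is an OLS
  mediator regression and paths b, c', c come from ridge-stabilised IRLS
  logistic fits (the ridge 1e-3 guards against separation in small
  subject-level fits); group estimates are subject means, with the
  mediated effect ab = mean_s(a_s b_s) so subject-level covariation of the
  paths is retained. Inference is a subjects-then-trials bootstrap with
  percentile CIs and two-tailed p values (percentile rather than
  bias-corrected; the choice is configurable in principle and flagged
  here). Default 5000 resamples; the original-scale 200,000 is reachable
  by argument. Logistic path coefficients live on the log-odds scale.
* **Confidence contrast and cluster test.** The per-subject contrast is
  exactly (high/no-change - low/no-change) + (high/change - low/change).
  Cells with one-sample |t| above the two-tailed p < .05 cluster-forming
  threshold are grouped under 4-connectivity; cluster mass is the summed
  t. The null is the extreme cluster mass over per-subject sign flips,
  built separately for positive and negative clusters; the reported
  corrected p is two-tailed (the one-sided (1+count)/(n_perm+1) estimate
  doubled). Testing each sign at its own 5% quantile would double the
  family-wise error; the two-tailed report keeps FWE at the nominal level,
  verified empirically at ~0.05 over simulated null datasets (24 subjects,
  30 x 30 matrices, 500 flips).

## Pipeline and reproducibility

`run_pipeline` chains simulate -> ddm-fit -> decode -> stats from one
schema-validated configuration (unknown keys rejected before any stage
runs). The global seed expands into per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`; every random operation
draws from a stage seed recorded in the run report, and identical
configurations give bitwise-identical report checksums (wall-clock timings
are excluded from the checksum). The bundled small configuration — 6
subjects x 160 trials, models {1, 4, 7, 10} at 2 chains x 1600 sweeps, a
16–32 channel decoding geometry on a 25 ms grid, 300 sign-flip
permutations and 1000 bootstrap resamples — runs in a few minutes on one
CPU and produces the DIC ladder, fixed-effect tables, mediation paths and
cluster p values.

## Known limitations

* The Euler–Maruyama generator has O(sqrt(dt)) boundary bias; at the
  default dt (0.5–1 ms) this is well inside the recovery tolerances, but
  exact-sampling comparisons at much tighter tolerances would need smaller
  steps.
* The mediation outcome model is logistic, so paths b/c/c' are log-odds
  quantities; total = direct + indirect holds only approximately on that
  scale.
* The variational logistic mixed model slightly shrinks fixed effects at
  small subject counts; tests assert recovery at tolerances that absorb
  this.
* Stage timings scale linearly in trials x timepoints for LOO decoding —
  the dominant cost at full geometry — and the pipeline exposes the grid
  step and trial cap precisely so that cost can be managed.
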