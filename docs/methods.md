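# Methods

## The observer model

Type-1 behaviour follows equal-variance Gaussian signal detection: on each
trial the observer receives evidence `x ~ N(±d'/2, 1)` (positive mean when
the "right" stimulus is the larger one) and responds "right" iff `x > c`.
Estimates use the closed forms `d' = z(H) − z(F)`, `c = −(z(H)+z(F))/2`,
with probabilities clipped to `[1e−6, 1 − 1e−6]` before the quantile
transform and every rating cell padded by `1/(2K)` (K = number of rating
levels, default 6). Padding is applied identically in the type-1 and type-2
fits so the two stages see the same data.

Type-2 behaviour is modelled in the meta-d' framework. On a meta-level
axis with unit-variance normals at `±meta_d/2` and the type-1 criterion
carried over in relative units (`meta_c = c' · meta_d`, `c' = c/d'`), K−1
type-2 criteria per response side partition each response region into
confidence bands. For "right" responses with ascending boundaries
`meta_c = b₀ < b₁ ≤ … < b_K = ∞`,

    P(conf = y | stim s, resp right) = [Φ(b_y − μ_s) − Φ(b_{y−1} − μ_s)] / [1 − Φ(meta_c − μ_s)]

with the mirrored lower-tail construction for "left" responses. Confidence
counts conditional on (stimulus, response) are multinomial in these
probabilities; only the equal-variance, response-nonconditional variant is
implemented (one shared meta_d, criteria fitted per side).

Derived measures: `Mratio = meta_d/d'`; `log(Mratio)` for analysis (refused
when `Mratio ≤ 0`, which instead triggers the exclusion screen); the
confidence criterion = mean `|type-2 c' − meta_c|` over the K−1 criteria of
each side, then averaged over sides. A configuration flag allows raw `c` as
the type-1 reference instead of `meta_c`; the meta-level anchor is the
default because the statistic is defined inside the meta-d' framework.

## Fitting

**MLE.** Parameters are `meta_d` (sign-unconstrained, so confidence
anti-correlated with accuracy can surface as `meta_d < 0` for the exclusion
screen) and log-increments of the two criteria ladders away from `meta_c`,
which guarantees ordering. The negative conditional log-likelihood and its
analytic gradient feed L-BFGS-B from three starts (`d'`, `0.25 d'`,
`−0.5 d'`); the best optimum is kept. Degenerate data (all confidence mass
in one rating) are fitted but flagged.

**Single-subject MCMC.** An affine-invariant ensemble sampler (emcee) over
`log Mratio` (prior N(0,1)) and the log-increments (priors N(0,2); the
increments' prior location is a fixed constant rather than tracking
`meta_c`, a simplification recorded here). `nburnin`/`nsamples` count
ensemble steps; each of the ~24 walkers contributes one draw per step.
Point estimates are posterior means; R-hat and effective sample size are
computed with arviz treating walkers as chains.

**Hierarchical model.** `lmr_s = log Mratio_s ~ N(mu + x_s'β, σ)` with
priors `mu, β_k ~ N(0,1)` and `σ ~ half-normal(1)`. The subject-level
type-2 likelihood enters through a *profile* likelihood: on a 49-point grid
of `log Mratio` in `[−4, 2]` the criteria are maximised out (warm-started
L-BFGS per grid point, walking outward from `Mratio = 1`), and the curve is
linearly interpolated during sampling. Criteria carry no cross-subject
structure, so profiling them keeps the sampled space at one dimension per
subject plus the group parameters; parameter-recovery and coverage tests
validate the resulting posterior summaries. The sampler is blocked
Metropolis-within-Gibbs: vectorised random-walk updates of all subject
effects (step sizes adapted to ~44% acceptance during burn-in), an exact
conjugate multivariate-normal draw of `(mu, β)`, a random-walk update of
`log σ`, and an interweaved non-centred (ASIS) re-update of `σ` that moves
`σ` and the subject effects jointly — without it the centred chain sticks
when `σ` is small. Several independent chains are run; arviz R-hat > 1.1
raises a recorded warning. Covariates are z-scored on entry by default
(the choice is recorded in the fit), and the design must be full-rank with
no missing values.

**HDI.** The narrowest contiguous window containing `⌈mass·n⌉` sorted draws,
leftmost on ties. An effect is "significant" when the 95% HDI excludes 0.

## Power analysis

Power of the F test of `p_tested` coefficients among `p_total` predictors:
noncentral F with `df1 = p_tested`, `df2 = n − p_total − 1` and
noncentrality `λ = f²·n` (the convention of the common G*Power module for
R² increase; it reproduces both reference numbers, n = 395 and 86%,
simultaneously, which the alternative `λ = f²·(df1+df2+1)` does not).
Defaults `p_total = 5, p_tested = 1` correspond to one symptom dimension
tested while controlling for the other two plus age and gender; both counts
are explicit parameters because the original calculator settings are not
fully determined.

## Synthetic data

**Designs.** Dot-numerosity task: 17 signed differences −64…+64 in 8-dot
steps (including the identical condition), 8 trials each over 2 blocks
(136 trials), reference box fixed at 272 dots, reference side
counterbalanced within condition (odd repetition counts are rejected).
Knowledge task: 8 log₁₀-population-ratio bins of width 0.225 per side
(16 signed conditions), 9 trials each over 2 blocks (144 trials); evidence
is abstracted as the signed bin index with the bin midpoint as physical
strength, and country pairs are opaque labels.

**Observers.** `x ~ N(k·e/2, 1)` for signed evidence `e` (so `d' = k·|e|`;
a saturating link is not currently provided — the linear link is the
default reading of a monotone psychometric curve), response by `x` vs the
criterion, confidence by cutting `x + ε, ε ~ N(0, meta_noise_sd)` with an
equal-width criteria ladder (first offset 0.4, spacing 0.35 in evidence
units) shifted rigidly by `confidence_shift` (floor 0.02 and a running
maximum keep the ladder ordered). Zero meta-noise and zero shift give
`Mratio = 1` by construction; meta-noise lowers fitted `Mratio`
monotonically. `simulate_model_counts` instead draws counts from the
meta-d' model itself, for recovery tests where the generative `Mratio` must
be exact.

**Cohorts.** Latent AD/CIT/SW factors are multivariate normal with 0.4
inter-factor correlations. 209 item responses are `loadings·factors +
noise` mapped linearly onto each instrument's ordinal range; the synthetic
weight matrix loads each instrument dominantly on its field-typical factor
(U(0.45, 0.85) dominant loadings, N(0, 0.08) cross-loadings), with
reverse-keyed items stored administered-coded and their weights negated.
The social-anxiety items are generated as separate fear and avoidance
answers and averaged. Big-5 latents couple to the symptom factors
(neuroticism–AD +0.5, extraversion–SW −0.3 by default). Demographics: age
~ N(25, 9) clipped at 18 (violators excepted), balanced binary gender.

**Planted effects.** Standardized effects on the *measured* confidence
criterion (defaults AD +0.33, CIT −0.17) are planted through
`confidence_shift`. The source variables are the cohort's own *scored*
symptom dimensions (recomputed from the generated items), so recovery by
the analysis chain is not attenuated by item noise; the structural part
`Σβ_k z_k` is completed with noise orthogonalised against the sources, so
the planted coefficients hold exactly in-sample and the regression recovers
them up to measurement noise alone (OLS intervals are therefore mildly
conservative for this generator). The measurement step is linearised with two calibration
constants estimated once by simulation at the default 136-trial design and
fixed (slope 0.855, residual variance 0.0108 in criterion² units); the
planted latent SD is 0.25 criterion units. Cohort observers use a ladder
starting at 0.55 (rather than the single-observer default 0.4) so that
planted negative shifts almost never reach the ordering floor, keeping the
shift→criterion map linear. Per-subject nuisance variation: lognormal
sensitivity (CV 0.15), criterion ~ N(0.05, 0.10) (slight "left" bias),
meta-noise ~ |N(0.25, 0.10)|.

**Planted violators** are guaranteed: under-18 ages, missing gender,
catch-item failures, constant confidence, > 4 knowledge non-responses, and
chance performers whose correct responses are flipped down to 48% accuracy
(emulating random or key-swapped responding) so the accuracy rule fires by
construction.

Everything is deterministic given the spec seed.

## What the generator does not emulate

Response times, learning/fatigue across blocks, sequential dependencies,
item-level idiosyncrasies (differential item functioning, acquiescence),
non-linear psychometric links, and real country-population content. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis chain* under the stated generative family, not robustness of the
scientific conclusions to real-data violations of it.

## Problem sizes used in the test suite

Unit tests run at reduced sizes chosen for tight feedback (hundreds of
trials, tens of subjects). The acceptance-level checks use: 100k trials for
ideal-observer calibration; 20 count tables (K = 2 and K = 4) against an
independent coordinate-refined grid-search oracle; 40 subjects × 400 trials
(group recovery) and 10 replicates of 100 subjects × 400 trials
(hierarchical regression) at reduced sampler settings (2 chains, 400
burn-in, 800 kept draws — scaled down from the 3 × 10,000-sample analysis
recipe); 500 null cohorts of n = 200 for the 5% false-positive calibration;
50 null replicates of 2 × 10 subjects for the HDI group test; and 20
replicates of the full n = 500 pipeline for planted-effect coverage.

## Known limitations

* The hierarchical likelihood is profiled, not marginal, over type-2
  criteria; posterior summaries agree with recovery targets, but subject-
  level uncertainty in criteria is not propagated.
* Group-level `exp(mu)` estimates sit slightly below the generative Mratio
  at small trial counts (geometric-vs-arithmetic mean attenuation of the
  log-normal measurement noise), well inside the ±0.1 tolerance at 400
  trials.
* Unequal-variance type-1 models, response-conditional meta-d', type-2 ROC
  measures and DIC model comparison are out of scope.
* The effect-planting calibration constants are valid for the default
  perception design; other designs require re-calibration (one pilot
  regression of measured criterion on planted shift).
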