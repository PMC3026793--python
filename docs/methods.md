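# Methods

This note records the models the package implements, the defaults it
ships with and why, and the numerical and design choices a maintainer
would otherwise have to reverse-engineer.

## Generative model of the synthetic cohort

The simulator produces the data structures the analysis assumes, at the
scale of a single-site case-control study: `n_controls = 25` and
`n_cp = 13` participants by default, ages from a normal distribution
truncated to [18, 80] whose location is solved (Brent's method) so the
truncated mean equals the configured 37.3 years (sd 17.9); gender and
the two media-consumption bands (TV, print; ordinal 1-4 for <1, 1-2,
3-7, >7 h/week) are categorical draws, uniform by default because no
cohort-level distribution is available to emulate.

A recognition trial is correct with probability
`invlogit(eta)`,

    eta = b0 + b_age * age_c + b_trial * target + b_rot * rotated
        + CP * (b_cp + b_cp_trial * target + b_cp_rot * rotated)
        + u0_i + u1_i * target

with `age_c = (age - 40)/10` (decades). Defaults: `b0 = 3.0` (a typical
control is right on ~95% of easy trials; cohort error rates land near
the 6-15% range such studies report), `b_age = -0.2` per decade,
`b_trial = -0.3`, `b_rot = -0.6`, and group effects taken from the
reported posterior estimates: `b_cp = -1.04`, `b_cp_trial = -1.63`
(the miss bias: CPs fail disproportionately on target trials),
`b_cp_rot = 0.31`. Random-intercept sd `sigma = 0.7` — chosen a priori
as a realistic between-participant spread (control accuracies roughly
0.85-0.99); the object-recognition preset lowers the baseline
(`b0 = 1.6`), weakens the group effect (`-0.40`), zeroes the
interactions and adds a random trial-type slope (sd 0.5), mirroring the
shoes experiment's structure. The famous-face (BFFT) model adds gender
and media-band effects with negative group x media interactions
(`-0.12` TV, `-0.30` print) so the media benefit is weaker for CPs;
40 recall items.

Trial schedules follow the design contract: two parts of
`8 x (4 targets + 16 distractors) = 160` presentations, part 1 rotated
and part 2 frontal, unconstrained random permutations (the source
design states no adjacency constraints), and four illumination labels
balanced over each target's repetitions with exactly one matching the
familiarization condition. Illumination is a label only — no generative
effect — because the analysis fits none.

Questionnaire totals (15 items, 1-5 each, total 15-75) are drawn for
CPs with Gaussian-copula correlation `rho = -0.55` to the participant's
latent ability, then decomposed into item ratings by uniformly random
composition; control totals are independent. The eight short-term tests
are emulated as already-standardized z-score columns: controls N(0,1),
each CP drawing one of four phenotypic archetypes (apperceptive
cascade, amnestic-only, face+object, diffuse; probabilities 4:4:3:4)
that shifts the relevant columns.

Everything derives from one master seed through named `SeedSequence`
substreams (stage name + participant index), so identical configs are
byte-identical across processes and partial stages can be re-run.

What the simulator does *not* emulate: item-level stimulus effects
(no crossed stimulus random effects — the analysis models participant
identity only), reaction times, learning/fatigue across a session, and
archetype coupling between the external short-term columns and the
trial-level long-term experiments (subtype structure in the external
columns is archetype-driven; long-term deficits are group-driven).
Passing tests therefore demonstrate the statistical machinery under the
assumed model, not robustness to stimulus heterogeneity or drift in
real data.

## Mixed-model estimation

`fit_glmm` maximizes the Laplace-approximated marginal likelihood of a
binomial logit GLMM, following the lme4 structure: for candidate
random-effect sds theta, a penalized joint Newton step (PIRLS) over
(beta, b) solves the conditional problem via a Schur complement on the
participant blocks, and the outer objective

    l(theta) = loglik(beta, b^) - 1/2 sum_i b_i' S^-1 b_i
             - 1/2 sum_i log det(I + S U_i' W_i U_i)

is maximized by a bounded deterministic scalar search (one variance
component) or Nelder-Mead (two; diagonal covariance — intercept and
slope are modelled independent). Trials with identical covariates
within a participant are aggregated to binomial counts first; because
the response is Bernoulli at trial level the aggregated kernel *is* the
trial log-likelihood (no binomial coefficients), so log-likelihoods and
LR tests are comparable across models that aggregate differently.
Wald SEs come from the Schur complement of the penalized information.
Convergence: PIRLS gradient < 1e-6; non-convergence and separation
(|beta| > 30) set a flag rather than raising. Cross-checks in the test
suite: plain-GLM path against statsmodels (1e-6), mixed path against
lme4::glmer (coefficients to 0.03, sigma to 0.01, log-likelihood to
0.1, LR statistics pairwise to ~0.01).

`predict_expected` marginalizes over random effects by Gauss-Hermite
quadrature (31 probabilists' nodes) or conditions at zero.

Posterior summaries use a seeded adaptive random-walk
Metropolis-within-Gibbs sampler over (beta, log sigma) on the
Laplace-integrated likelihood, with the stated priors: N(0, 1e10) per
fixed effect and inverse Wishart (df = 1, scale = the unconditional
response variance; univariately an inverse gamma) on sigma^2. Proposal
scales adapt toward 44% acceptance during burn-in only, so the
post-burn-in chain is a valid fixed-kernel sampler and identical seeds
give identical summaries. The posterior mode is the kernel-density peak
of the marginal chain (512-point grid); the HPDI is the shortest
interval containing 95% of samples; convergence is gated on split
R-hat < 1.05 across chains.

### Likelihood-ratio calibration

The LR test's chi-square reference is asymptotic in the number of
participants for between-participant effects. The packaged null
calibration (`calibration.lr_null_simulation`) therefore defaults to a
cohort of 150 + 150 participants with 40 trials each, where the
reference holds (empirically ~5-6% rejection at alpha = 0.05 and a
Kolmogorov-Smirnov-compatible chi-square(1) null distribution of D). At
the study's own size (25 + 13) the same simulation shows the reference
is mildly anti-conservative — p-values somewhat too small — which is
the known caveat that motivates reporting Bayesian interval estimates
alongside LR tests for interaction effects; rerun the function with a
study-sized config to reproduce that behaviour.

## Abnormality scores

Residuals are observed-minus-expected per participant with the expected
value averaged over the participant's own trial covariates. Two scales
are implemented:

- **logit (default):** observed performance enters as the empirical
  logit `log((y + 0.5)/(m - y + 0.5))`; the expectation is the control
  model's *conditional* (zero-random-effect) prediction, Haldane-
  corrected identically, so a participant performing exactly as
  predicted has residual exactly zero. A participant's residual is then
  approximately their own random effect plus delta-method binomial
  noise — approximately normal, which is what the downstream t-based
  deficit call assumes.
- **response:** plain proportions, with the expectation marginalized
  over the random effects by quadrature, so null residuals average
  exactly zero on the probability scale.

The logit default is a deliberate choice: near ceiling (control
accuracy ~0.92 here) the inverse-logit transform makes response-scale
residuals left-skewed, and simulation shows the single-case t-test then
flags ~7-8% of null controls instead of 5%; on the logit scale the
test holds its nominal level (the suite's 2000-replicate calibration).
The residual scale is monotone-irrelevant to ranks but not to tail
calibration.

Leave-one-out control models re-estimate the fixed effects per fold
(warm-started at the full fit; variance parameters held at the full-fit
values by default — `refit_variance=True` refits them too). The fold
refits run at the aggregated-array level, which is algebraically
identical to dropping the participant's rows and keeps a 25-control
cohort at ~25 ms per full LOO pass; a brute-force per-fold direct
likelihood maximization agrees to 1e-6 in the tests. The *unconditional*
control residual variance is used for standardization (not a
conditional-on-covariates variance): simpler, and consistent with
comparing profiles across many tests at the cost of slightly inflated
|z| for participants with extreme covariates.

Aggregate (category) scores are the mean of the available member-column
z-scores — at least one member suffices, so participants with partial
batteries still receive summary scores — re-standardized against the
control distribution of that mean. The category map (which test belongs
to perceptual / associative / mnestic and faces / shoes) is data, not
code: the default maps reaction-time and presentation-time-threshold
tests to perceptual, rotated-view and restricted-time generalization to
associative, the one-year and famous-face tests to mnestic, with
category summaries over the face tests and class totals over faces,
shoes and everything.

Deficit calls are one-sided (lower tail only): the procedure flags
deficits, not supra-normal performance. No multiple-comparison
correction is applied across cells — deliberately mirrored from the
source procedure and noted here rather than "fixed". Externally
standardized columns are negated at ingestion when larger raw values
mean worse performance (reaction times), then re-standardized against
the ingested control rows.

## Group comparisons

`wilcoxon_rank_sum` reports W in the Mann-Whitney-U-of-the-first-sample
convention (0 <= W <= n_x n_y; swapping samples maps W to n_x n_y − W),
computed by scipy with exact enumeration when both n <= 10 and no ties,
else the tie-corrected continuity-corrected normal approximation. The
direction of every one-sided comparison must be passed explicitly.
`rank_correlation` is Spearman's rho on midranks with an exact
permutation p for n <= 8 (all n! pairings; scipy's t approximation
above that); Pearson is selectable since the estimator behind a printed
"rho" is not always stated.

## Subtyping

Profile distances are Euclidean over the six summary columns by
default, with pairwise-complete rescaling `sqrt(m / m_shared)` so
partially observed profiles remain comparable (this can violate the
triangle inequality; complete linkage does not require it). The
agglomeration is implemented directly because its contract pins
deterministic tie-breaking: ties in merge height resolve toward the
clusters containing the lexicographically smallest participant labels,
and leaf order puts the child containing the smallest label first —
making the whole tree equivariant under permutations of the input rows.
scipy's `linkage` is the cross-check oracle for merge heights. The
cluster count is not fixed anywhere; the dendrogram is the deliverable
and `cut_clusters(k)` is offered for convenience. Clustering runs over
all participants in the pipeline (controls anchor the normal range);
the planted-archetype recovery check clusters the CP rows, whose
partition is the quantity of interest.

## Pipeline

`run_pipeline` executes simulate → sdt → fit → scores → group → cluster,
writing every intermediate as CSV/JSON with a SHA-256 manifest; stage
failures abort with the stage name. A cohort with no CPs skips group
comparisons with a warning but still runs the control calibration
machinery. Posterior summaries for interaction effects are off by
default in the pipeline (`bayesian: true` enables them) since they
dominate runtime; the optional heatmap is the only plot.

## Problem sizes used in validation

The packaged checks run at deliberately modest sizes chosen to make the
statistical assertions sharp: deficit-test calibration at 2000
simulated cohorts of 25 + 1 participants in the test suite
(3-binomial-SE band around the nominal 5%) and 5000 cohorts in the
reproduction script, LR null calibration at 500 cohorts of 300
participants,
parameter recovery at 100 study-sized cohorts (bias bound 0.1 logit),
subtype recovery at 100 planted cohorts (adjusted Rand > 0.8 in >= 90%),
and Monte-Carlo oracles at 10^4-4x10^5 draws where closed forms are
checked.

## Known limitations

- Random-effect covariance is diagonal; correlated intercept-slope
  pairs are not modelled.
- No crossed stimulus random effects (participant grouping only).
- The Laplace approximation is used for the likelihood everywhere;
  adaptive quadrature beyond the marginal-prediction step is not
  implemented.
- The single-case procedure standardizes by the unconditional control
  variance, so abnormality scores for participants with extreme
  covariate values are mildly exaggerated (in both groups).
- The deficit classification is marginally conservative in simulation
  (empirical false-positive rate a little under the nominal 5%),
  because control residuals carry leave-one-out estimation noise that
  the held-out case's residual does not share in full.
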