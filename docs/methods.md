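# Methods

This note records the modelling assumptions, parameter defaults, and
numerical choices behind `rcstroke`. It complements the API docstrings;
nothing here asserts empirical values that the test suite or
`scripts/acceptance.py` do not themselves compute.

## 1. Ordinal outcome model

### Specification

For an ordinal outcome with ordered levels indexed `0..J` and a slope
vector `beta` over `p` covariate terms,

    P(Y <= j | x) = F(theta_j - x . beta),    F = logistic,

with `theta_0 < theta_1 < … < theta_{J-1}` (proportional odds /
cumulative link, logit). Positive `beta` shifts mass toward higher
(worse) levels; `exp(beta_k)` is the cumulative odds ratio for a
one-unit increase in term `k`, identical across all level splits.

Design construction (`DesignSpec`, `build_design`): main-effect columns
are taken as-is (no centering or scaling — coefficients stay in the
outcome scale per raw covariate unit); an interaction `a:b` is the
elementwise product. Outcome levels are mapped to consecutive ranks of
the *observed* levels only, so a cohort in which some NIHSS values never
occur gets exactly `J_obs − 1` thresholds; the AIC parameter count
`k = p + J_obs − 1` follows the same convention.

### Estimation

Maximum likelihood by Newton iterations with analytic gradient and
Hessian. The monotonicity constraint is removed by the standard
reparameterization

    zeta_0 = theta_0,   zeta_j = log(theta_j - theta_{j-1})  (j >= 1),

and derivatives are chain-ruled through the Jacobian. Details that
matter in practice:

- **Damping.** Away from the optimum the reparameterized Hessian can be
  indefinite (the curvature term of the chain rule). When the smallest
  eigenvalue of `−H` is not safely positive, a Levenberg shift
  `(|lambda_min| + 1e-6 (1 + |lambda_min|)) I` is added before solving;
  if the solve still fails, a normalized gradient step is used.
- **Line search.** Step halving (up to 60 halvings) accepting any
  strict likelihood increase.
- **Convergence.** Either gradient max-norm `< 1e-8`, or Newton
  decrement `0.5 g.step < 1e-12 (1 + |loglik|)` — in which case the
  final step is still applied before declaring convergence. The
  decrement criterion is needed because with raw-unit covariates (age
  ~ 64, volume×count products ~ 10^3) the information matrix has
  condition number ~ 10^6 and the gradient norm stalls near 1e-7 at
  the double-precision optimum.
- **Separation.** If a slope exceeds ±30 during iteration, or the final
  deviance is numerically zero, the fit is flagged `converged = False`,
  slopes are capped, and a warning names possible (quasi-)separation.
  This arises legitimately in small subgroup fits.

Fits agree with `statsmodels` `OrderedModel` to 1e-5 in parameters and
1e-6 in log-likelihood on random problems (tested), and reduce exactly
to binary logistic regression when `J = 1` split (tested to 1e-6).

### Inference

The variance matrix is the inverse observed information in natural
parameters `(thresholds, beta)`, symmetrized; a pseudo-inverse is used
(with a warning) if the information matrix is singular. Wald z-tests,
two-sided p-values, and log-scale-symmetric odds-ratio confidence
intervals follow. Nested models fitted on the same rows and outcome
levels are compared by the likelihood-ratio chi-square with
`df = k_full − k_nested`.

## 2. Lesion scoring

A region counts as *affected* when at least one voxel of the binary
lesion mask lies inside it — a deliberate, reproducible threshold; no
minimum-overlap fraction is applied. `N_total` is the number of
affected labeled regions, `N_RC` the number of affected rich-club
regions (0–12), and lesion volume is mask voxel count × voxel volume
(reported in cc).

Inputs are NIfTI label volumes with a TSV sidecar
(`label, name, hemisphere, is_rich_club`) and per-patient binary masks
named `<id>.nii.gz`. Masks must be on the atlas grid: shape, voxel
dimensions (1e-3 mm tolerance), and axis orientation are checked and
all failures reported together. Masks whose values are not {0, 1}
(within 1e-6) are rejected rather than thresholded silently. Patients
without a mask file are excluded with a logged warning; duplicate ids
are an error.

## 3. Synthetic cohort generator

The generator reproduces the joint structure the analysis assumes, with
defaults matching the reference cohort's published marginals (n = 344):

| quantity | marginal | defaults |
|---|---|---|
| age | normal truncated at 18 y | mean 64.59, sd 15.76 |
| sex (male = 1) | Bernoulli | P(male) = 0.64 |
| DWIv (lesion volume, cc) | log-normal, moment-matched | mean 15.01, sd 30.00 |
| N_RC | negative binomial, truncated at 12 | mean 1.33, sd 1.27 |
| N_other | negative binomial, truncated at 30 | mean 2.3, sd 2.0 |

Moment matching is exact on the untruncated laws: the log-normal uses
`sigma^2 = log(1 + CV^2)`, `mu = log(mean) − sigma^2/2`; the negative
binomial uses `r = mean^2/(var − mean)` (Poisson fallback if not
over-dispersed).

**Volume–count coupling.** DWIv and N_RC are tied by a Gaussian copula
between the log-DWIv latent and the N_RC latent score. The default
copula correlation is **0.93**: because the heavy-tailed log-normal and
the discretized count attenuate latent correlation, 0.93 is what
induces the intended *raw-scale* behaviour — Pearson(DWIv, N_RC) ≈ 0.69
and a variance inflation factor ≈ 1.9 for N_RC in the main-effects
design (both recomputed at n = 100 000 in the tests and acceptance
script). A latent value of 0.69 would give VIF ≈ 1.3 and raw
correlation ≈ 0.5, i.e. understate the collinearity the analysis must
tolerate. `N_other` is coupled to DWIv the same way, and
`N_total = max(N_RC + N_other, 1)`.

**Outcomes.** mRS (levels 0–6) and NIHSS (0–42) are drawn from the
proportional-odds law with slope vectors set to the reference
coefficient table (mRS: age .05, sex .78, age:sex −.02, DWIv .05,
N_RC .33, DWIv:N_RC −.01; NIHSS: .03, .9, −.02, .08, .57, −.01). The
cut-points are not published; they are calibrated so that the *expected*
marginal over the simulated covariates matches target category
proportions exactly (solving `mean_i F(theta_j − eta_i) = cumsum(p)_j`
by bracketed root-finding). Target proportions come from a truncated-
geometric (one-parameter, right-skewed) shape over the levels whose
mean equals the published outcome mean (mRS 1.68, NIHSS 5.58) — an
assumption, since only means and sds are published; it produces
realistic right-skewed stroke-scale distributions.

**What the generator does not emulate:** site/rater effects, the
empirical NIHSS zero-inflation, missing data, and any nonlinear
volume–outcome relationship beyond the fitted interaction. Recovered-
parameter means over replicate cohorts exhibit the usual small-sample
MLE bias of ordinal logit (~+0.02 on a slope of 0.33 at n = 344), and
`E[exp(beta_hat)] > exp(E[beta_hat])` by Jensen's inequality; both are
visible in the acceptance outputs.

**Image phantoms.** `make_synthetic_atlas` places 6 mirrored bilateral
pairs of spherical rich-club regions (labels 1–12, one-voxel
disjointness margin) plus optional non-rich-club spheres on a 2 mm
grid. `sample_lesion_mask` grows an ellipsoid anchored on the target
regions' voxels until it intersects exactly the requested rich-club
subset, verifying the result and raising after bounded retries rather
than returning an unverified mask. Scoring these phantoms recovers the
intended `N_RC` exactly (tested).

## 4. Cohort analysis

- **Model battery**: per outcome, `baseline`
  (age + sex + DWIv + age:sex), `richclub` (+ N_RC + DWIv:N_RC), and
  `richclub` without interactions; LRT comparisons baseline-vs-richclub
  (df = 2) and no-interaction-vs-richclub (df = 2). A cohort with
  constant `N_RC` raises a degenerate-outcome error instead of fitting
  a non-identified model.
- **Subgroup**: patients with `N_RC = 0` refitted with `N_total` in
  place of `N_RC` (does a plain region count carry information when the
  rich club is spared?). Fewer than 30 rows warns; zero rows errors.
- **Stability**: for each of `repetitions` random partitions into `k`
  near-equal folds, the model is refit on every leave-one-fold-out
  subset (`k` refits per repetition; no held-out evaluation — the
  target is coefficient stability, not prediction). Reported per term:
  mean and sd of the odds ratio and the count of refits with two-sided
  Wald p ≥ 0.05. Folds with a single outcome level are skipped and
  logged; more than 5% skipped is an error.
- **Diagnostics**: VIF via OLS `1/(1 − R^2)` on the main effects;
  ICC(2,1) (two-way random effects, absolute agreement, single rater —
  the appropriate form for interchangeable raters scoring the same
  patients; matches `pingouin` to 1e-8 in tests); Spearman rank
  correlation via average ranks with the t-approximation (matches
  `scipy` including ties).

## 5. Known limitations

- The proportional-odds assumption is imposed, not tested; no
  partial-proportional or score test is provided.
- Threshold calibration matches the target marginal in expectation,
  not per realization; single-cohort statistics (and therefore
  single-cohort stability summaries) inherit full sampling variability
  of the cohort itself, with cross-cohort sd of the fitted `N_RC` odds
  ratio ≈ 0.15 at n = 344.
- Wald intervals are used throughout; no profile likelihood.
- Lesion phantoms are ellipsoids — adequate for exercising the scoring
  contract, not morphologically realistic.
- `vcov` is the observed (not expected) information inverse; the two
  coincide for the canonical logit link at the MLE only asymptotically.
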