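# Methods

## Model

For each of k correlated Gaussian longitudinal responses, subject i carries
a linear mixed submodel

    y_ℓij = x′_1ij β_ℓ + z′_1ij b_ℓi + ε_ℓij,   ε_ℓij ~ N(0, σ_ℓ²),

and a parametric Weibull time-to-event submodel whose density, with shape
α_ℓ and linear predictor η_ℓi on the log-hazard scale, is

    f(t | b_ℓi) = [α t^{α−1} e^{η}]^{δ} exp(−t^{α} e^{η}),
    η_ℓi = x′_2i ξ_ℓ + θ′_ℓ b_ℓi.

Setting α = 1 recovers the exponential model exactly. The association
parameter θ_ℓ couples the two submodels through the shared random effect.
In the multivariate model the random intercepts (b_1i, …, b_ki) are jointly
Gaussian with SDs d_ℓ and correlation matrix {ρ_rs}; the k = 1 variant also
supports a random intercept + slope with its own 2×2 covariance and two
association parameters (θ₁ for the intercept, θ₂ for the slope).

Residuals are conditionally independent given the random effect
(Σ_i = σ_ℓ² I). This matches estimating a single residual SD per response
and keeps every per-subject likelihood factor a product of univariate
Gaussians.

### Sign convention

The default (`log_hazard`) enters η into the hazard as written above, so a
larger η means a larger hazard and shorter survival. A `negated` option
maps η ↦ −η, under which positive coefficients lengthen survival — the
convention implied by reading Weibull coefficients on the accelerated
scale. The generator and the fitter always share one convention, so
parameter-recovery results are identical under either choice.

## Marginal likelihood and quadrature

Marginal likelihoods integrate the conditional joint density against the
Gaussian random-effect density with adaptive tensor-product Gauss–Hermite
quadrature (default Q = 9 nodes per dimension, configurable). Per subject,
a damped Newton search (the log-integrand is strictly concave) finds the
integrand mode m_i and curvature H_i; nodes are placed at
m_i + √2 C_i u_q with C_i C_i′ = (−H_i)⁻¹ and the usual exp(‖u_q‖²)
reweighting. If the mode search fails for a subject the code falls back to
prior-whitened non-adaptive centering there and logs a warning. Supported
integral dimensions are 1–3 (univariate models, bivariate pairs, and the
full trivariate model); beyond three dimensions the pairwise route is the
supported estimator.

A plain Monte-Carlo integrator over the same integrand (sampling random
effects from their prior, with a delta-method standard error) serves as an
independent oracle in the tests; it is never used for fitting.

## Pairwise composite-likelihood estimation

All P = k(k−1)/2 bivariate joint models are maximized separately. Within a
pair (r, s) each factor carries its own survival contribution — the
composite-likelihood construction taken literally — and in `per_response`
survival mode each factor uses its own response's event time (exactly how
the generator writes the data); `shared` mode duplicates the single
observed time in both factors.

Optimization is quasi-Newton (BFGS) on an unconstrained scale (log σ,
log d, log α, atanh ρ) with analytic gradients. The parameter score is
computed at fixed quadrature centering as the posterior-weighted average of
the integrand's parameter derivatives; the centering itself tracks the
parameters during the main pass and is frozen for a final polishing pass so
the reported gradient norm refers to an exactly consistent
objective/gradient pair. Convergence tolerances (gradient 1e−6, mode search
1e−8, at most 500 iterations) are implementation choices. Non-convergence
of a pair is recorded, not raised; its estimates are excluded from
averaging, and only when a parameter loses every copy does estimation
abort.

Duplicate estimates (each response-specific parameter appears in k−1
pairs) are averaged. The covariance of the averaged vector is the sandwich

    Cov(Λ̂′) = J⁻¹ K J⁻¹,   Cov(Λ̂) = A Cov(Λ̂′) A′,

with J block-diagonal in the per-pair observed information (central
differences of the analytic score), K the empirical outer product of
concatenated per-subject scores — nonzero across pairs because pairs share
subjects — and A the averaging matrix (entries 1/(k−1), and 1 for each
ρ_rs, which has a single source pair). The assembled k×k correlation
matrix is descriptive: if it is not positive semidefinite it is reported
as such, never projected or re-used for fitting.

Individual-parameter p-values are two-sided normal approximations from the
sandwich SEs; the joint association test is the multivariate Wald statistic
W² = (Lθ̂)′(L Cov(θ̂) L′)⁻¹(Lθ̂) ~ χ²_rank(L).

## Synthetic-data generator

The generator draws from the model itself at the reference design:
N = 1000 subjects, 7 annual visits (t = 0..6), k = 3 responses with
β₁ = (3.7, −1, 0.5), β₂ = (4, 1, −0.5), β₃ = (5, 1, −0.5), σ = (0.8, 1, 1),
d = (0.7, 0.5, 0.5), ρ₁₂ = −0.5, ρ₁₃ = 0.6, ρ₂₃ = 0.3, survival
coefficients ξ = (5, −0.5) on (intercept, male) with male ~ Bernoulli(0.5),
θ = (−0.8, 0.6, −0.5), α = 0.5. Event times come by inversion,
T = (−log U · e^{−η})^{1/α}. Two deliberate literalisms: each response gets
its own event time (`per_response`), and longitudinal visits are generated
at all 7 occasions regardless of the event time. There is no censoring by
default (δ = 1 everywhere); an administrative censoring time is available
as an option. Replicate r uses seed base_seed + r, so studies are
reproducible and resumable by replicate ID.

What this emulates: measurement-error-laden trajectories whose subject
level correlates across responses and drives the hazard. What it does not:
informative dropout, visit-time irregularity, missingness, truncation of
trajectories at the event, or covariate-dependent censoring — passing
recovery tests here says nothing about those features of real cohort data.

The baseline-values-only Weibull comparator refits each response's survival
model with the subject's earliest observed value (which includes
measurement error) as a fixed covariate in place of the latent intercept.
Classical errors-in-variables attenuation then shrinks the association
coefficient by roughly d²/(d² + σ²), e.g. from −0.8 toward ≈ −0.35 for the
first response — the contrast the comparator exists to demonstrate.

## Problem sizes used by the shipped checks

The test suite replicates the study at a reduced scale chosen for a desk
run: R = 100 replicates at N = 500 with Q = 9 for pairwise recovery, and
R = 200 null replicates at N = 300 for the joint-Wald type-I calibration
(the empirical sandwich covariance is a large-sample estimator; at much
smaller N its SEs are noticeably downward-biased, as is typical of
score-based sandwich estimators).
The acceptance script uses R = 60 (pairwise + comparator) and runs the
full trivariate likelihood on 12 replicates. Full-scale replication
(R = 1000, N = 1000, complete full-likelihood arm, Monte-Carlo SE ratios)
is supported through the same `replicate_study`/CLI path but takes hours
on one core.

## Design choices that were genuinely open

- Initialization uses closed-form moment decompositions (OLS fixed
  effects, within/between residual variance split) and a survival-only
  Weibull fit, with θ = 0 and ρ from per-subject mean-residual
  correlations clipped to (−0.9, 0.9). A full LMM fit at initialization
  would be slower for no measurable benefit; the LMM enters instead as an
  independent oracle in the tests.
- α is a per-response parameter (the generator uses a common value, but
  estimates are reported per response); the exponential variant pins every
  α at 1.
- The full trivariate fit, when run alongside the pairwise fit, is warm
  started from the pairwise averages.
- Failed replicates are excluded by replicate ID when methods are
  compared, mirroring matched-ID comparison; convergence rates are always
  reported alongside.

## Known limitations

- Tensor quadrature limits the full-likelihood oracle to k ≤ 3; the
  pairwise estimator itself has no such limit but is only exercised here
  up to k = 4 (pair enumeration).
- Only right censoring is modelled; a single association scale θ_ℓ is
  assumed constant over time.
- The assembled cross-response correlation matrix may fall outside the
  positive-semidefinite cone in small samples; it is flagged, not
  repaired.
- No composite-likelihood model-selection criteria (AIC/BIC analogues) or
  likelihood-ratio machinery across non-nested pairwise fits is provided.
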