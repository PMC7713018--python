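# mvjoint

Joint models for **multiple correlated Gaussian longitudinal responses and a
parametric time-to-event outcome**, estimated by **pairwise bivariate
composite likelihood** with sandwich standard errors.

The package is aimed at biostatisticians analysing cohort data in which
several biomarkers (say, log lipid and inflammation trajectories) are
measured repeatedly per subject, correlate with each other, and each may be
associated with a survival endpoint. Fitting the full multivariate joint
model is numerically hard because the random-effect integral grows with the
number of responses k; the pairwise strategy instead fits all
P = k(k−1)/2 bivariate joint models and averages the duplicated parameter
estimates, at almost no efficiency cost.

## Model

Per response ℓ, a linear mixed submodel and a Weibull survival submodel
share a subject-level random effect b_ℓi:

    y_ℓij = x′_1ij β_ℓ + z′_1ij b_ℓi + ε_ℓij,        ε_ℓij ~ N(0, σ_ℓ²)
    f(t_i | b_ℓi) = [α t^{α−1} e^{η_ℓi}]^{δ_i} exp(−t^{α} e^{η_ℓi}),
    η_ℓi = x′_2i ξ_ℓ + θ_ℓ b_ℓi

with α = 1 giving the exponential model. θ_ℓ measures the
longitudinal–survival association; the random intercepts across responses
are jointly Gaussian with correlations ρ_rs, which capture the
interdependence of the trajectories. Marginal likelihoods are computed by
adaptive Gauss–Hermite quadrature; estimates are quasi-Newton MLEs with
analytic scores, and averaged pairwise estimates get the
J⁻¹KJ⁻¹-type sandwich covariance that accounts for pairs sharing subjects.
See `docs/methods.md` for the full account.

## Worked example

```python
from mvjoint import (SimulationDesign, simulate_dataset, pairwise_fit,
                     wald_joint_association, effect_multiplier, summarize)

design = SimulationDesign(n_subjects=500)   # reference 3-response design
data = simulate_dataset(design, seed=314)
fit = pairwise_fit(data, design.model_spec())

w2, df, p = wald_joint_association(fit)
print(f"joint Wald: W2={w2:.2f}, df={df}, p={p:.2e}")
print(summarize(fit))
```

prints (abridged):

```
joint Wald: W2=184.41, df=3, p=9.83e-40
Combined joint model fit over responses: y1, y2, y3
pairs fitted: 3, converged: 3
Longitudinal
  beta[y1][0]    3.6715 (0.0504)   z= 72.830  p=0.0000
  ...
  sigma[y1]      0.7816 (0.0103)   z= 75.649  p=0.0000
  d[y1][0]       0.6876 (0.0254)   z= 27.062  p=0.0000
Survival
  xi[y1][0]      5.2343 (0.2102)   z= 24.900  p=0.0000
  xi[y1][1]     -0.4458 (0.1084)   z=-4.114  p=0.0000
  theta[y1][0]  -0.9331 (0.0841)   z=-11.093  p=0.0000
  alpha[y1]      0.5306 (0.0215)   z= 24.715  p=0.0000
  ...
Correlation
  rho[y1,y2]    -0.4986 (0.0486)   z=-10.260  p=0.0000
  rho[y1,y3]     0.5739 (0.0454)   z= 12.646  p=0.0000
  rho[y2,y3]     0.4056 (0.0627)   z= 6.465  p=0.0000
```

The W² statistic tests the joint null that all three association
parameters θ are zero (here overwhelmingly rejected — the data were
generated with θ = (−0.8, 0.6, −0.5)). Each table row is an averaged
pairwise estimate with its combined sandwich SE. A survival coefficient is
read through its time multiplier, e.g.
`effect_multiplier(-0.9204) → (0.3984, 0.6016)`: a group with that
coefficient has about 60% shorter survival time.

A command-line interface mirrors the library:

```sh
mvjoint simulate --out sim/ --seed 7            # write CSVs at the reference design
mvjoint fit --config cfg.yaml --longitudinal sim/longitudinal.csv \
            --survival sim/survival.csv --method pairwise --out fit/
mvjoint replicate --config cfg.yaml --reps 100 --out study/ [--resume]
```

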