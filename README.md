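# reefvar

Hierarchical vector-autoregressive state-space analysis of coral-reef
benthic composition.

Coral-reef monitoring programmes produce transect time series of the
proportional cover of hard coral, macroalgae and other benthos.  Two
questions matter for conservation planning: how much of the long-run
variability in reef composition is a persistent property of individual
sites (so that a single survey can identify high-value sites), and how
likely is a site — or a randomly-chosen site in the region — to spend
its future at ecologically damaging coral cover (<= 10% of hard
substrate)?  `reefvar` answers both with a Bayesian VAR(1) state-space
model of ilr-transformed compositions:

    x_{i,t+1} = a + alpha_i + B x_{i,t} + eps_{i,t},   eps ~ N(0, Sigma)
    alpha_i ~ N(0, Z),        y_{i,j,t} ~ t2(x_{i,t}, H, nu)

with per-site random intercepts `alpha_i` and a heavy-tailed bivariate-t
transect layer.  From the fitted posterior the package derives the
stationary laws `N(mu_i*, Sigma*)` (fixed site) and `N(mu*, Sigma* + Z*)`
(random site), the variance partition `rho = sqrt(|Sigma*|/|Sigma*+Z*|)`,
snapshot-vs-long-term correlations, the low-cover probabilities
`q_{kappa,i}` and `q_kappa` by 1-D quadrature, and gradient/elasticity
sensitivities of `q_kappa` in all 12 structural parameters.  A
synthetic-survey generator reproduces the structure of the East African
(Kenya/Tanzania, 1991-2013) monitoring design — 30 sites on 20 reefs,
289 site visits, 2,665 transects — for recovery experiments and
among-site-variability sweeps.  See `docs/methods.md` for the science.

## Worked example

```python
from reefvar import ReefVAR, generate_survey, paper_like_design, paper_like_params

records = generate_survey(paper_like_params(), paper_like_design(seed=1), seed=1)
model = ReefVAR(chains=2, warmup=700, iters=700, seed=2).fit(records)
print(f"rho   = {model.rho_:.2f}")
print(f"q_0.1 = {model.regional_q_:.2f}")
print(f"nu    = {model.nu_:.2f}")
print(f"snapshot correlations = {model.snapshot_corr_.round(2)}")
```

On the synthetic survey above this prints (MCMC is seeded, so exactly
reproducible; takes a few minutes):

```
rho   = 0.30
q_0.1 = 0.07
nu    = 2.89
snapshot correlations = [0.85 0.79]
```

meaning: within-site temporal variability accounts for only ~30% of the
long-run dispersion of reef composition (among-site differences
dominate, so site-level conservation choices are meaningful); a
randomly-chosen site spends ~7% of its long-term future at coral cover
<= 0.1; the transect layer is strongly heavy-tailed (nu ~ 3); and a
single accurate snapshot of a site correlates ~0.8 with its
long-term mean, so one survey is already informative.
`model.site_risk_` tabulates per-site `q_{0.1,i}` with HPD bounds, and
`model.sensitivity()` ranks the structural parameters by their effect
on the regional risk.

A command-line interface mirrors the library:

```sh
reefvar simulate --seed 1 --out survey.csv
reefvar summarize --data survey.csv
reefvar fit --data survey.csv --chains 4 --iter 1000 --warmup 1000 --seed 0 --out results/
```

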