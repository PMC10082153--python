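# commocc — community occupancy analysis for camera-trap surveys

`commocc` is a Python package for hierarchical multispecies (community)
occupancy analysis of camera-trap data. It is written for wildlife
ecologists who have a stack of camera-trap detections, a handful of site
covariates, and the usual problem: animals occupy sites they are never
photographed at. The package takes raw timestamped triggers all the way to
posterior summary tables, with every stage testable against synthetic
surveys that carry full ground truth.

## The model

For species *k*, site *i* and sampling occasion *j*, detection histories
are modelled with a latent occupancy state (Royle–Dorazio community
occupancy):

```
z_ik  ~ Bernoulli(ψ_ik)              true occupancy (unobserved)
y_ikj ~ Bernoulli(z_ik · p_k)        imperfect detection
```

Species borrow strength through community-level distributions on the logit
scale. The **null** variant summarises the community:

```
logit(ψ_k) ~ Normal(μ_lψ, σ_lψ),   ψ̄ ~ Beta(1,1),  μ_lψ = logit(ψ̄),  σ_lψ ~ U(0,5)
logit(p_k) ~ Normal(μ_lp, σ_lp)    (mirrored hyperpriors)
```

The **covariate** variant makes occupancy site-specific through a
logit-linear model with species-level coefficients drawn from community
distributions:

```
logit(ψ_ik) = β_0k + Σ_x β_xk · cov_xi
β_xk ~ Normal(μ_x, σ_x),   μ_x ~ U(−5, 5),   σ_x ~ U(0, 5)
```

optionally with a bivariate-normal correlation between a species'
occupancy intercept and its detection logit (widespread species tend to be
easier to detect). Models are fitted by a Metropolis-within-Gibbs sampler
with exact latent-state updates, adaptive proposal scales (frozen before
retention), multiple independently seeded chains, Gelman–Rubin Rhat and
effective-sample-size diagnostics, and an iterate-until-converged driver
that doubles the chain length while any Rhat ≥ 1.05.

Upstream of the model the package implements the standard camera-trap
preparation steps: sequential triggers within a configurable gap (default
60 s) collapse into single independent detections (a livestock herd firing
the camera every 30 s counts once), detections are binned into 14-day
occasions, and site covariates are screened (Pearson |r| ≥ 0.7, VIF ≥ 10)
and z-scored before fitting.

## Worked example

Simulate a study-scale survey (15 species, 34 sites, six 14-day occasions,
community mean detection ≈ 0.10, occupancy ≈ 0.6, strong positive
community effects of livestock presence and canopy cover) and analyse it:

```sh
commocc simulate --out survey --preset paper_like --variant covariate --seed 1
printf 'n_iter: 2500\nn_adapt: 500\nn_burn: 500\nrhat_threshold: 1.1\nmax_rounds: 2\n' > config.yaml
commocc fit --events survey/events.csv --covariates survey/covariates.csv \
            --out fit --config config.yaml --seed 1
```

which prints

```
null model: converged after 1 round(s)
covariate model: converged after 1 round(s)
outputs in fit
```

`fit/community_null.csv` then holds the community-level summaries on the
probability scale (posterior mean, sd, 95% credible interval, Rhat, ESS,
overlap0 and the f statistic). For this seed:

| parameter | mu | sd | lci | uci | overlap0 |
|-----------|------|------|------|------|----|
| p   | 0.077 | 0.023 | 0.037 | 0.128 | 0 |
| psi | 0.582 | 0.134 | 0.334 | 0.896 | 0 |

i.e. the community-average detection probability per 14-day occasion is
about 0.08 and community-average occupancy about 0.58 — close to the
generating values (0.10, 0.6), with the credible intervals reflecting a
34-site survey's uncertainty. `fit/community_covariate.csv` holds the
community slope summaries for this realization (all three effects positive,
livestock strongest, none of the intervals covering zero):

| parameter | mu | sd | lci | uci | overlap0 |
|-----------|------|------|------|------|----|
| canopy_pct        | 3.86 | 0.78 | 2.10 | 4.94 | 0 |
| dist_settlement_m | 2.81 | 0.77 | 1.50 | 4.49 | 0 |
| livestock_n       | 4.12 | 0.58 | 2.75 | 4.95 | 0 |

Per-species detection/occupancy summaries and caterpillar-plot data land in
`fit/species_*.csv` and `fit/species_effects.csv`; a human-readable summary
comes from

```sh
commocc report --community fit/community_null.csv --species fit/species_null.csv
```

Everything is seed-deterministic: the same seed reproduces every output
byte for byte, and each run writes a `manifest.json` recording the config
hash and derived seeds.

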