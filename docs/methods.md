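# Methods

This note records the statistical model, the numerical choices behind the
sampler, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem left room.

## Model

Detection histories are binary: `y[k,i,j] = 1` if species *k* produced at
least one independent detection at site *i* during occasion *j*. The
occupancy state `z[k,i]` is latent; conditional on it, occasions are
independent Bernoulli trials with species-specific detection probability
`p_k`. Marginally, the likelihood of a site history is
`ψ·Π p^y (1−p)^(1−y) + (1−ψ)·1{all zero}` over occasions with effort —
a proper distribution over the 2^J histories (verified by enumeration in
the tests).

Community structure: species-level logit-scale parameters are normal draws
around community means. The community mean occupancy and detection
probabilities carry Beta(1,1) priors **on the probability scale**; on the
logit scale that is a standard-logistic density, not a flat prior, and the
sampler treats it as such (a flat-on-logit treatment would fail the
prior-recovery check below). Community sds are Uniform(0,5); community
covariate-slope means are Uniform(−5,5) — sensible ranges only for
logit-scale effects of unit-variance covariates, which is why the pipeline
standardizes covariates by default (raw-scale fitting is a flag, and the
standardization transform is stored so slopes can be back-converted).

The covariate variant optionally couples each species' occupancy intercept
and detection logit through a bivariate normal with correlation
ρ ~ Uniform(−1,1). The coupling is a modelling assumption — the tendency of
widespread species to be more detectable — and can be toggled off
(`ModelSpec.correlated`); results should state the toggle. The variant
default is on for the covariate model, off for the null model. Detection is
modelled without covariates.

Species never detected during the survey are excluded before fitting: the
model describes the detected community, and no data-augmentation for unseen
species is attempted.

## Sampler

Metropolis-within-Gibbs, chosen for transparency over Pólya-Gamma
augmentation:

* `z[k,i]` has an exact Bernoulli full conditional
  (`ψ(1−p)^J / (ψ(1−p)^J + 1−ψ)` when nothing was seen, 1 otherwise) and is
  Gibbs-updated each sweep.
* Species-level logit parameters use Gaussian random-walk Metropolis,
  vectorised across species (conditionally independent given the
  hyperparameters). The site-by-species log-likelihood term uses the
  identity `z·logσ(η) + (1−z)·logσ(−η) = logσ((2z−1)η)` and a cached
  per-species row-sum, refreshed only on acceptance.
* Community slope means μ_x have truncated-normal full conditionals under
  their uniform priors and are Gibbs-drawn exactly (inverse-CDF). The
  remaining hyperparameters use scalar random-walk Metropolis. The sd
  parameters are proposed on their own scale with the Uniform(0,5) prior
  rejecting out-of-support moves — a simpler kernel than a log-scale
  reflected walk, with the same invariant distribution.
* Two joint translation moves shift a community mean together with all its
  species effects. The group-prior terms cancel exactly, so the acceptance
  ratio involves only the likelihood and the logistic hyperprior. Without
  these moves the hierarchy's location mixes an order of magnitude slower
  (measured ESS for μ_lψ under the prior: ~13 vs ~35 per 1000 draws, and
  visibly biased KS statistics at practical chain lengths).

Proposal scales adapt toward 0.44 acceptance (the scalar random-walk
optimum) by a Robbins–Monro rule with gain decaying as 1/√batch, in
batches of 25 sweeps during a dedicated adaptation phase, and are frozen
before burn-in ends, so all retained draws come from a fixed, detailed-
balance-preserving kernel. Default protocol mirrors the common Gibbs-engine
settings: 3 chains × 50,000 retained iterations, 1000 adaptation sweeps,
1000 burn-in, no thinning; every count is configurable and test suites use
far shorter chains. Whether a published 50,000-iteration run includes
burn-in is typically ambiguous, so both interpretations are reachable
through the config.

Chains are seeded by spawning independent `SeedSequence` children from one
master seed; identical configs give bit-identical draws. Initialization:
`z = 1` wherever detected, Bernoulli(0.5) elsewhere; logit parameters from
Normal(0,1); hyper-sds from Uniform(0.5, 2); a bounded number of
re-initializations guards against a non-finite start.

Fitting an entirely effortless dataset is normally an input error, but
`run_chains(..., allow_empty=True)` permits it: with no information the
chains must reproduce the prior, and the tests verify the posterior of ψ̄
is Uniform(0,1) by Kolmogorov–Smirnov distance.

## Diagnostics and summaries

Rhat is the classic (non-split) multi-chain Gelman–Rubin factor,
`sqrt(((n−1)/n·W + B/n)/W)` — matching the reporting convention of the
Gibbs-sampling engines this workflow descends from; split-Rhat is available
behind a flag. ESS pools chains: `N/(1 + 2Στ)` with chain-averaged
autocorrelations truncated by Geyer's initial positive sequence. Constant
chains have undefined diagnostics and report NaN with a warning rather than
failing.

Summary tables carry mean, sd, 2.5/50/97.5% quantiles (linear
interpolation between order statistics), Rhat, ESS, `overlap0` (does the
95% interval contain zero) and `f` (fraction of draws sharing the sign of
the posterior mean). Credible level defaults to 95%, the cited engines'
convention where a table labels LCI/UCI without a level. Probability-scale
community summaries apply the inverse logit to the hyperparameter draws and
summarize the transformed draws; medians are equivariant under the
monotone transform, means are not, and both scales are reported for the
community intercept because published tables are sometimes ambiguous about
which scale an intercept row is on.

`converge_or_extend` refits with doubled `n_iter` (fresh derived seeds)
while any parameter's Rhat ≥ 1.05, up to `max_rounds`, returning an
unconverged flag rather than raising — pipelines should report, not crash.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
with every drawn quantity stored as ground truth:

* **Covariates.** Canopy cover: gamma truncated to [0,100]%, parameters
  solved so the truncated distribution has mean 21.1, sd 22.2 (open
  rangeland with a forested tail). Settlement distance: lognormal, mean
  1592.9 m, sd 1205.2 m. Livestock detections: negative binomial, mean
  24.8, sd 47.3 (strongly overdispersed — most sites see few herds, a few
  see many). These match the surveyed study area's reported moments and are
  all overridable.
* **Community.** Species parameters drawn from the community
  distributions; `z ~ Bernoulli(ψ)`, `y ~ Bernoulli(z·p)`. The
  `paper_like` preset uses the study scale — 15 species, 34 sites, six
  14-day occasions, ψ̄ ≈ 0.6, p̄ ≈ 0.10, community slopes (canopy 2.2,
  distance 1.5, livestock 3.1 on the logit scale of standardized
  covariates) with sd 1 — so qualitative orderings of effects can be
  checked. The `recovery` preset enlarges to 25 species × 150 sites because
  34 sites carry little information about hyper-sds.
* **Trigger streams.** Each detection becomes a run of three 30-s-spaced
  triggers placed inside its occasion with a safety margin; livestock herds
  emit runs of known length at 30-s spacing, placed in non-overlapping
  slots. Collapsing and binning the stream therefore reproduces the
  generating matrix exactly, and the per-site collapsed livestock count
  equals the `livestock_n` covariate by construction.

What the generator does **not** emulate: camera failures (effort gaps must
be supplied explicitly), spatial autocorrelation in covariates or
occupancy, within-occasion temporal clustering of wild-species visits,
species' movement or home ranges, and misidentification. Passing tests
therefore demonstrate correctness of the algebra, the sampler and the
calibration under the model's own assumptions — not robustness to
violations of them.

## Problem sizes used in validation

The acceptance layer runs: exhaustive likelihood enumeration (J ≤ 4);
1,000 random latent-state configurations against brute force (1e-12);
a 1-species × 3-site toy against dense-grid posterior integration
(tolerance 0.02, 3 × 5,000 iterations); 20 replicate communities at
25 species × 150 sites × 6 occasions with 3 × 4,000-iteration chains for
credible-interval calibration (≥ 15/20 coverage, ≥ 19/20 correct slope
signs); prior recovery at 12,000 retained draws (KS < 0.05); and AR(1)/
shifted-chain oracles for ESS and Rhat. The headline script
(`scripts/acceptance.py`) analyses one `paper_like` survey with
3 × 2,500-iteration chains per model variant — chain lengths chosen as
comfortable for a 34-site survey's posterior, with the convergence driver
doubling them if Rhat exceeds 1.1.

## Known limitations

* Detection covariates and species-richness augmentation are out of scope.
* The ψ–ρ correlation parameterization is one reasonable construction; the
  literature it follows does not pin down a unique form.
* The classic Rhat is insensitive to some within-chain pathologies that
  split-Rhat catches; use the flag for suspicious fits.
* With 34 sites and rare species, hyper-sd posteriors lean on their priors;
  interval widths at that scale should be read accordingly.
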