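"""Metropolis-within-Gibbs sampler for the community occupancy models.

The latent occupancy states z_ik have exact Bernoulli full conditionals and
are Gibbs-updated every iteration.  Species-level logit-scale parameters are
updated by Gaussian random-walk Metropolis, vectorised across species (they
are conditionally independent given the hyperparameters).  Community slope
means mu_x have truncated-normal full conditionals under their Uniform(-5,5)
priors and are Gibbs-updated exactly; the remaining hyperparameters
(community means with logistic priors, sds with Uniform(0,5) priors, the
psi–p correlation) use scalar random-walk Metropolis.

Proposal scales adapt toward a 0.44 acceptance rate (the scalar random-walk
optimum) during a dedicated adaptation phase and are frozen before any draw
is retained, preserving detailed balance for the retained chains.  Chains
are seeded independently and deterministically from a single master seed:
the same configuration always yields bit-identical draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_expit, ndtr, ndtri

from .camtrap_data import DetectionMatrix, SiteCovariates
from .msom_core import (
    ModelSpec,
    _bvn_logpdf,
    _logistic_logpdf,
    _norm_logpdf,
)

TARGET_ACCEPT = 0.44


# ---------------------------------------------------------------------------
# Configuration and draw containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """Chain-length and seeding configuration.

    Defaults mirror a JAGS-style protocol: 3 chains, 1000 adaptation
    iterations, 1000 burn-in, 50,000 retained iterations, no thinning.
    """

    n_iter: int = 50_000
    n_chains: int = 3
    n_adapt: int = 1000
    n_burn: int = 1000
    thin: int = 1
    master_seed: int = 0
    init_step: float = 0.5
    adapt_batch: int = 25

    def __post_init__(self):
        for name in ("n_iter", "n_chains", "n_adapt", "n_burn", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.init_step <= 0 or self.adapt_batch < 1:
            raise ValueError("init_step and adapt_batch must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, one (n_chains, n_iter) array per parameter.

    Species-level parameters are named ``lp[species]``, ``lpsi[species]``,
    ``beta0[species]`` and ``beta[species,covariate]``; hyperparameters keep
    their plain names (``mu_lpsi``, ``sigma_lp``, ``mu_x[covariate]``, ...).
    """

    draws: dict[str, np.ndarray]
    species_ids: list[str]
    spec: ModelSpec
    config: SamplerConfig

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iter(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[name].reshape(-1)

    def to_frame(self):
        """Wide DataFrame (chain, iteration, one column per parameter)."""
        import pandas as pd

        C, N = self.n_chains, self.n_iter
        out = {
            "chain": np.repeat(np.arange(C), N),
            "iteration": np.tile(np.arange(N), C),
        }
        for name, arr in self.draws.items():
            out[name] = arr.reshape(-1)
        return pd.DataFrame(out)

    def to_inference_data(self):
        """Convert to an ArviZ InferenceData (for trace plots, cross-checks)."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.draws.items()})


# ---------------------------------------------------------------------------
# Elementary kernels
# ---------------------------------------------------------------------------

def conditional_z_prob(y_history, psi: float, p: float, effort_mask=None) -> float:
    """Exact full-conditional P(z = 1 | y, psi, p) for one species-site.

    Any detection forces z = 1; otherwise Bayes' rule over the two latent
    states gives psi (1-p)^J / (psi (1-p)^J + 1 - psi) with J the number of
    occasions that had effort.
    """
    y = np.asarray(y_history, dtype=int)
    if effort_mask is None:
        effort_mask = np.ones_like(y, dtype=bool)
    effort_mask = np.asarray(effort_mask, dtype=bool)
    if y[effort_mask].any():
        return 1.0
    J = int(effort_mask.sum())
    q = psi * (1.0 - p) ** J
    return float(q / (q + 1.0 - psi))


def metropolis_step(current: float, log_target, step: float, rng) -> tuple[float, bool]:
    """One scalar Gaussian random-walk Metropolis step.

    Returns (new value, accepted).  The target must be finite at the current
    state — a -inf there means the chain left the support, an internal
    invariant violation.
    """
    lt0 = log_target(current)
    if not np.isfinite(lt0):
        raise RuntimeError(f"log target not finite at current state {current!r}")
    prop = current + step * rng.standard_normal()
    lt1 = log_target(prop)
    if np.log(rng.random()) < lt1 - lt0:
        return float(prop), True
    return float(current), False


def adapt_steps(
    steps,
    accepted,
    proposed,
    batch_index: int,
    target: float = TARGET_ACCEPT,
):
    """Robbins–Monro update of proposal scales from a batch's acceptance rate.

    The gain decays as 1/sqrt(batch) so scales settle; rates above the target
    widen the proposal, rates below shrink it.
    """
    steps = np.asarray(steps, dtype=float)
    rate = np.asarray(accepted, dtype=float) / max(1, proposed)
    gain = min(0.5, 1.0 / math.sqrt(max(1, batch_index)))
    return steps * np.exp(gain * (rate - target))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class _ChainState:
    """Mutable single-chain state with cached likelihood ingredients."""

    def __init__(self, data: DetectionMatrix, x_sites, spec: ModelSpec, rng):
        self.spec = spec
        self.rng = rng
        self.K, self.I, self.J = data.y.shape
        self.X = spec.n_covariates
        mask = data.effort_mask                     # (I, J)
        self.J_i = mask.sum(axis=1).astype(float)   # active occasions per site
        self.n_det = (data.y * mask[None, :, :]).sum(axis=2).astype(float)  # (K, I)
        self.det_any = self.n_det > 0               # (K, I)
        self.x_sites = x_sites                      # (I, X) or None

        # --- initialization ---
        K, I, X = self.K, self.I, self.X
        self.z = np.where(self.det_any, 1.0, (rng.random((K, I)) < 0.5).astype(float))
        s = {}
        s["lp"] = rng.standard_normal(K)
        if spec.variant == "null":
            s["lpsi"] = rng.standard_normal(K)
            s["mu_lpsi"] = float(rng.standard_normal())
            s["sigma_lpsi"] = float(rng.uniform(0.5, 2.0))
        else:
            s["beta0"] = rng.standard_normal(K)
            s["beta"] = rng.standard_normal((K, X))
            s["mu_0"] = float(rng.standard_normal())
            s["sigma_0"] = float(rng.uniform(0.5, 2.0))
            s["mu_x"] = rng.uniform(-1.0, 1.0, X)
            s["sigma_x"] = rng.uniform(0.5, 2.0, X)
            if spec.use_correlation:
                s["rho"] = float(rng.uniform(-0.5, 0.5))
        s["mu_lp"] = float(rng.standard_normal())
        s["sigma_lp"] = float(rng.uniform(0.5, 2.0))
        self.s = s

        # proposal scales and acceptance bookkeeping, one entry per block
        self.steps: dict[str, np.ndarray] = {}
        self.acc: dict[str, np.ndarray] = {}
        for name in self._block_names() + ["shift_occ", "shift_det"]:
            shape = np.shape(self.s.get(name, 0.0))
            self.steps[name] = np.full(shape if shape else (), 0.5, dtype=float)
            self.acc[name] = np.zeros(shape if shape else (), dtype=float)
        self._refresh_eta()
        self._refresh_det_sums()

    # -- bookkeeping ---------------------------------------------------

    def _block_names(self):
        names = ["lp", "mu_lp", "sigma_lp"]
        if self.spec.variant == "null":
            names += ["lpsi", "mu_lpsi", "sigma_lpsi"]
        else:
            names += ["beta0", "beta", "mu_0", "sigma_0", "sigma_x"]
            if self.spec.use_correlation:
                names += ["rho"]
        return names

    def _block(self, name):
        return self.s[name]

    def _refresh_eta(self):
        if self.spec.variant == "null":
            self.eta = self.s["lpsi"][:, None]           # (K, 1), broadcasts
        else:
            self.eta = self.s["beta0"][:, None] + self.s["beta"] @ self.x_sites.T

    def _refresh_det_sums(self):
        self.d1 = (self.z * self.n_det).sum(axis=1)      # detections at occupied sites
        self.dJ = self.z @ self.J_i                      # occasions at occupied sites

    # -- Gibbs z update -------------------------------------------------

    def update_z(self):
        psi = expit(np.broadcast_to(self.eta, (self.K, self.I)))
        log_miss = self.J_i[None, :] * log_expit(-self.s["lp"])[:, None]
        q1 = psi * np.exp(log_miss)
        prob = q1 / (q1 + 1.0 - psi)
        draw = self.rng.random((self.K, self.I)) < prob
        self.z = np.where(self.det_any, 1.0, draw.astype(float))
        self.zsign = 2.0 * self.z - 1.0
        self.ll_occ = self._occ_rowsums(self.eta)  # cache; eta unchanged here
        self._refresh_det_sums()

    # -- species-level vector Metropolis --------------------------------

    def _occ_rowsums(self, eta):
        # z binary ⇒ z·log σ(η) + (1−z)·log σ(−η) = log σ((2z−1)·η)
        zsum = self.z.sum(axis=1)
        if eta.shape[1] == 1:  # psi constant across sites
            e = eta[:, 0]
            return zsum * log_expit(e) + (self.I - zsum) * log_expit(-e)
        return log_expit(self.zsign * eta).sum(axis=1)

    def _species_prior_occ(self, beta0, lp):
        s = self.s
        if self.spec.variant == "null":
            return _norm_logpdf(beta0, s["mu_lpsi"], s["sigma_lpsi"])
        if self.spec.use_correlation:
            return _bvn_logpdf(beta0, lp, s["mu_0"], s["mu_lp"], s["sigma_0"],
                               s["sigma_lp"], s["rho"])
        return _norm_logpdf(beta0, s["mu_0"], s["sigma_0"])

    def _species_prior_det(self, lp, beta0):
        s = self.s
        if self.spec.variant == "covariate" and self.spec.use_correlation:
            return _bvn_logpdf(beta0, lp, s["mu_0"], s["mu_lp"], s["sigma_0"],
                               s["sigma_lp"], s["rho"])
        return _norm_logpdf(lp, s["mu_lp"], s["sigma_lp"])

    def _accept_vector(self, name, delta_target, cur, prop):
        acc = np.log(self.rng.random(cur.shape)) < delta_target
        self.acc[name] += acc
        return np.where(acc, prop, cur), acc

    def update_lp(self):
        s = self.s
        occ_anchor = s["lpsi"] if self.spec.variant == "null" else s["beta0"]
        cur = s["lp"]
        prop = cur + self.steps["lp"] * self.rng.standard_normal(self.K)

        def ll(lp):
            return (self.d1 * log_expit(lp) + (self.dJ - self.d1) * log_expit(-lp)
                    + self._species_prior_det(lp, occ_anchor))

        new, _ = self._accept_vector("lp", ll(prop) - ll(cur), cur, prop)
        s["lp"] = new

    def update_occupancy_params(self):
        s = self.s
        if self.spec.variant == "null":
            cur = s["lpsi"]
            prop = cur + self.steps["lpsi"] * self.rng.standard_normal(self.K)

            def ll(v):
                return (self._occ_rowsums(v[:, None])
                        + _norm_logpdf(v, s["mu_lpsi"], s["sigma_lpsi"]))

            new, _ = self._accept_vector("lpsi", ll(prop) - ll(cur), cur, prop)
            s["lpsi"] = new
            self._refresh_eta()
            self.ll_occ = self._occ_rowsums(self.eta)
            return

        # intercepts
        cur = s["beta0"]
        d = self.steps["beta0"] * self.rng.standard_normal(self.K)
        eta_prop = self.eta + d[:, None]
        ll_prop = self._occ_rowsums(eta_prop)
        delta = (
            ll_prop - self.ll_occ
            + self._species_prior_occ(cur + d, s["lp"])
            - self._species_prior_occ(cur, s["lp"])
        )
        new, acc = self._accept_vector("beta0", delta, cur, cur + d)
        s["beta0"] = new
        self.eta = np.where(acc[:, None], eta_prop, self.eta)
        self.ll_occ = np.where(acc, ll_prop, self.ll_occ)

        # slopes, one covariate at a time
        for x in range(self.X):
            cur = s["beta"][:, x]
            d = self.steps["beta"][:, x] * self.rng.standard_normal(self.K)
            eta_prop = self.eta + d[:, None] * self.x_sites[:, x][None, :]
            ll_prop = self._occ_rowsums(eta_prop)
            delta = (
                ll_prop - self.ll_occ
                + _norm_logpdf(cur + d, s["mu_x"][x], s["sigma_x"][x])
                - _norm_logpdf(cur, s["mu_x"][x], s["sigma_x"][x])
            )
            prop_acc = np.log(self.rng.random(self.K)) < delta
            self.acc["beta"][:, x] += prop_acc
            s["beta"][:, x] = np.where(prop_acc, cur + d, cur)
            self.eta = np.where(prop_acc[:, None], eta_prop, self.eta)
            self.ll_occ = np.where(prop_acc, ll_prop, self.ll_occ)

    # -- hyperparameter updates ------------------------------------------

    def _scalar_mh(self, name, log_target, index=None):
        step = self.steps[name] if index is None else self.steps[name][index]
        cur = self.s[name] if index is None else self.s[name][index]
        new, accepted = metropolis_step(cur, log_target, float(step), self.rng)
        if index is None:
            self.s[name] = new
            self.acc[name] += accepted
        else:
            self.s[name][index] = new
            self.acc[name][index] += accepted

    def update_hypers(self):
        s, spec = self.s, self.spec
        sig_max = spec.sigma_max

        if spec.variant == "null":
            lpsi = s["lpsi"]

            self._scalar_mh("mu_lpsi", lambda m: float(
                _norm_logpdf(lpsi, m, s["sigma_lpsi"]).sum() + _logistic_logpdf(m)))
            self._scalar_mh("sigma_lpsi", lambda g: -np.inf if not 0 < g < sig_max
                            else float(_norm_logpdf(lpsi, s["mu_lpsi"], g).sum()))
            lp = s["lp"]
            self._scalar_mh("mu_lp", lambda m: float(
                _norm_logpdf(lp, m, s["sigma_lp"]).sum() + _logistic_logpdf(m)))
            self._scalar_mh("sigma_lp", lambda g: -np.inf if not 0 < g < sig_max
                            else float(_norm_logpdf(lp, s["mu_lp"], g).sum()))
            return

        # covariate variant: slope hyperparameters
        K = self.K
        for x in range(self.X):
            bx = s["beta"][:, x]
            # mu_x: exact truncated-normal Gibbs draw (flat prior truncates)
            m, sd = float(bx.mean()), float(s["sigma_x"][x] / math.sqrt(K))
            b = spec.mu_x_bound
            lo, hi = ndtr((-b - m) / sd), ndtr((b - m) / sd)
            u = lo + self.rng.random() * (hi - lo)
            s["mu_x"][x] = m + sd * float(ndtri(np.clip(u, 1e-12, 1 - 1e-12)))

            self._scalar_mh(
                "sigma_x",
                lambda g, bx=bx, x=x: -np.inf if not 0 < g < sig_max
                else float(_norm_logpdf(bx, s["mu_x"][x], g).sum()),
                index=x,
            )

        beta0, lp = s["beta0"], s["lp"]

        def pair_ll(mu0, mulp, s0, slp, rho):
            if spec.use_correlation:
                return float(_bvn_logpdf(beta0, lp, mu0, mulp, s0, slp, rho).sum())
            return float(_norm_logpdf(beta0, mu0, s0).sum()
                         + _norm_logpdf(lp, mulp, slp).sum())

        rho = s.get("rho", 0.0)
        self._scalar_mh("mu_0", lambda m: pair_ll(m, s["mu_lp"], s["sigma_0"],
                                                  s["sigma_lp"], rho)
                        + float(_logistic_logpdf(m)))
        self._scalar_mh("sigma_0", lambda g: -np.inf if not 0 < g < sig_max
                        else pair_ll(s["mu_0"], s["mu_lp"], g, s["sigma_lp"], rho))
        self._scalar_mh("mu_lp", lambda m: pair_ll(s["mu_0"], m, s["sigma_0"],
                                                   s["sigma_lp"], rho)
                        + float(_logistic_logpdf(m)))
        self._scalar_mh("sigma_lp", lambda g: -np.inf if not 0 < g < sig_max
                        else pair_ll(s["mu_0"], s["mu_lp"], s["sigma_0"], g, rho))
        if spec.use_correlation:
            self._scalar_mh("rho", lambda r: -np.inf if not -1 < r < 1
                            else pair_ll(s["mu_0"], s["mu_lp"], s["sigma_0"],
                                         s["sigma_lp"], r))

    # -- joint translation moves ------------------------------------------
    #
    # Random-walk updates of a community mean mix slowly because the species
    # effects must follow it one at a time.  Shifting the mean and every
    # species effect by the same delta leaves the group prior terms
    # invariant (all deviations unchanged), so the Metropolis ratio reduces
    # to the likelihood change plus the logistic hyperprior change — a cheap
    # move that decorrelates the hierarchy's location.

    def update_shift_occ(self):
        s = self.s
        delta = float(self.steps["shift_occ"]) * self.rng.standard_normal()
        mu_name = "mu_lpsi" if self.spec.variant == "null" else "mu_0"
        eff_name = "lpsi" if self.spec.variant == "null" else "beta0"
        eta_prop = self.eta + delta
        ll_prop = self._occ_rowsums(eta_prop)
        log_ratio = float(
            ll_prop.sum() - self.ll_occ.sum()
            + _logistic_logpdf(s[mu_name] + delta) - _logistic_logpdf(s[mu_name])
        )
        if np.log(self.rng.random()) < log_ratio:
            s[mu_name] = float(s[mu_name] + delta)
            s[eff_name] = s[eff_name] + delta
            self.eta = eta_prop
            self.ll_occ = ll_prop
            self.acc["shift_occ"] += 1

    def update_shift_det(self):
        s = self.s
        delta = float(self.steps["shift_det"]) * self.rng.standard_normal()
        lp_prop = s["lp"] + delta
        ll_cur = self.d1 * log_expit(s["lp"]) + (self.dJ - self.d1) * log_expit(-s["lp"])
        ll_prop = self.d1 * log_expit(lp_prop) + (self.dJ - self.d1) * log_expit(-lp_prop)
        log_ratio = float(
            ll_prop.sum() - ll_cur.sum()
            + _logistic_logpdf(s["mu_lp"] + delta) - _logistic_logpdf(s["mu_lp"])
        )
        if np.log(self.rng.random()) < log_ratio:
            s["mu_lp"] = float(s["mu_lp"] + delta)
            s["lp"] = lp_prop
            self.acc["shift_det"] += 1

    # -- one sweep -------------------------------------------------------

    def sweep(self):
        self.update_z()
        self.update_lp()
        self.update_occupancy_params()
        self.update_hypers()
        self.update_shift_occ()
        self.update_shift_det()

    def adapt(self, batch_index: int, batch_size: int):
        for name in self.steps:
            self.steps[name] = adapt_steps(
                self.steps[name], self.acc[name], batch_size, batch_index
            )
            self.acc[name] = np.zeros_like(self.acc[name])

    # -- recording --------------------------------------------------------

    def record_names(self, species_ids, covariate_names):
        names = []
        if self.spec.variant == "null":
            names += ["mu_lpsi", "sigma_lpsi"]
        else:
            names += ["mu_0", "sigma_0"]
            names += [f"mu_x[{c}]" for c in covariate_names]
            names += [f"sigma_x[{c}]" for c in covariate_names]
            if self.spec.use_correlation:
                names += ["rho"]
        names += ["mu_lp", "sigma_lp"]
        for sp in species_ids:
            names.append(f"lp[{sp}]")
        if self.spec.variant == "null":
            names += [f"lpsi[{sp}]" for sp in species_ids]
        else:
            names += [f"beta0[{sp}]" for sp in species_ids]
            for sp_idx, sp in enumerate(species_ids):
                names += [f"beta[{sp},{c}]" for c in covariate_names]
        return names

    def record_values(self):
        s = self.s
        vals = []
        if self.spec.variant == "null":
            vals += [s["mu_lpsi"], s["sigma_lpsi"]]
        else:
            vals += [s["mu_0"], s["sigma_0"]]
            vals += list(s["mu_x"])
            vals += list(s["sigma_x"])
            if self.spec.use_correlation:
                vals += [s["rho"]]
        vals += [s["mu_lp"], s["sigma_lp"]]
        vals += list(s["lp"])
        if self.spec.variant == "null":
            vals += list(s["lpsi"])
        else:
            vals += list(s["beta0"])
            vals += list(s["beta"].reshape(-1))
        return vals


def run_chains(
    data: DetectionMatrix,
    cov: SiteCovariates | None,
    spec: ModelSpec,
    config: SamplerConfig,
    allow_empty: bool = False,
) -> PosteriorDraws:
    """Fit the model by Metropolis-within-Gibbs; fully seed-deterministic.

    Species with all-zero detection histories are dropped before fitting
    (the model covers detected species).  ``allow_empty=True`` keeps them
    and permits a zero-effort dataset, in which case the chains sample the
    prior — useful for prior-recovery checks.
    """
    if not allow_empty:
        if not data.effort_mask.any():
            raise ValueError("dataset has zero survey effort at every site")
        data = data.drop_undetected_species()
        if data.n_species == 0:
            raise ValueError("no species with at least one detection")
    x_sites = None
    if spec.variant == "covariate":
        if cov is None:
            raise ValueError("covariate variant requires site covariates")
        if not cov.standardized:
            raise ValueError("covariate variant requires standardized covariates")
        cov = cov.aligned_to(list(data.site_ids))
        x_sites = cov.table[spec.covariates].to_numpy(dtype=float)

    seeds = np.random.SeedSequence(config.master_seed).spawn(config.n_chains)
    draws: dict[str, np.ndarray] | None = None
    names: list[str] | None = None

    for c, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        chain = _init_chain(data, x_sites, spec, rng)
        if names is None:
            names = chain.record_names(data.species_ids, spec.covariates)
            draws = {n: np.empty((config.n_chains, config.n_iter)) for n in names}
        store = np.empty((config.n_iter, len(names)))
        batch = 0
        for it in range(config.n_adapt):
            chain.sweep()
            if (it + 1) % config.adapt_batch == 0:
                batch += 1
                chain.adapt(batch, config.adapt_batch)
        for _ in range(config.n_burn):
            chain.sweep()
        kept = 0
        for it in range(config.n_iter * config.thin):
            chain.sweep()
            if (it + 1) % config.thin == 0:
                store[kept] = chain.record_values()
                kept += 1
        for idx, n in enumerate(names):
            draws[n][c] = store[:, idx]

    return PosteriorDraws(draws=draws, species_ids=list(data.species_ids),
                          spec=spec, config=config)


def _init_chain(data, x_sites, spec, rng, max_attempts: int = 10) -> _ChainState:
    """Initialize a chain, re-drawing on the (rare) non-finite start."""
    for _ in range(max_attempts):
        chain = _ChainState(data, x_sites, spec, rng)
        # one trial sweep verifies every conditional is finite at the start
        try:
            chain.sweep()
        except RuntimeError:
            continue
        return chain
    raise RuntimeError("failed to initialize the sampler at a finite posterior point")
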