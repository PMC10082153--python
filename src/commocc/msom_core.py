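"""Hierarchical multispecies occupancy model: parameters, priors, densities.

The model (Royle–Dorazio community occupancy) treats each detected species'
occupancy and detection parameters as draws from community-level normal
distributions on the logit scale:

Null (community-summary) variant, species k, site i, occasion j::

    z_ik ~ Bernoulli(psi_k)                       latent occupancy
    y_ikj | z_ik ~ Bernoulli(z_ik * p_k)          imperfect detection
    logit(psi_k) ~ Normal(mu_lpsi, sigma_lpsi)
    logit(p_k)   ~ Normal(mu_lp,   sigma_lp)

with hyperpriors psi_bar ~ Beta(1,1), mu_lpsi = logit(psi_bar),
sigma_lpsi ~ Uniform(0,5), and the mirrored structure on detection.
Note the Beta(1,1) prior lives on the *probability* scale; on the logit
scale it is the standard-logistic density, not a flat prior.

Covariate variant: occupancy becomes site-specific through a logit-linear
model logit(psi_ik) = beta0_k + sum_x beta_xk * cov_xi with species slopes
beta_xk ~ Normal(mu_x, sigma_x), mu_x ~ Uniform(-5, 5),
sigma_x ~ Uniform(0, 5), and intercept hyperpriors mirroring the null
model's (Beta(1,1) on the probability scale for the community mean).
Optionally the species pair (beta0_k, logit p_k) gets a bivariate-normal
prior with correlation rho ~ Uniform(-1, 1), capturing the tendency of
widespread species to also be easier to detect.

The sampler state is a flat dict of logit-scale parameters; probabilities
are always derived, never stored clamped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, log_expit, logit

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityHyperParams:
    """Community-level hyperparameters of the null model."""

    psi_bar: float
    sigma_lpsi: float
    p_bar: float
    sigma_lp: float

    def __post_init__(self):
        if not (0 < self.psi_bar < 1 and 0 < self.p_bar < 1):
            raise ValueError("psi_bar and p_bar must lie in (0, 1)")
        # sigma = 0 is admitted for degenerate-hierarchy simulation; the
        # sampler itself never leaves the open (0, 5) prior support
        if not (0 <= self.sigma_lpsi < 5 and 0 <= self.sigma_lp < 5):
            raise ValueError("sigma_lpsi and sigma_lp must lie in [0, 5)")

    @property
    def mu_lpsi(self) -> float:
        return float(logit(self.psi_bar))

    @property
    def mu_lp(self) -> float:
        return float(logit(self.p_bar))


@dataclass
class CovariateHyperParams:
    """Community-level hyperparameters of the covariate model."""

    beta0_bar: float
    sigma_0: float
    p_bar: float
    sigma_lp: float
    mu_x: np.ndarray      # per-covariate community mean slope, logit scale
    sigma_x: np.ndarray   # per-covariate slope sd
    rho_corr: float = 0.0

    def __post_init__(self):
        self.mu_x = np.atleast_1d(np.asarray(self.mu_x, dtype=float))
        self.sigma_x = np.atleast_1d(np.asarray(self.sigma_x, dtype=float))
        if not (0 < self.beta0_bar < 1 and 0 < self.p_bar < 1):
            raise ValueError("beta0_bar and p_bar must lie in (0, 1)")
        if not (0 <= self.sigma_0 < 5 and 0 <= self.sigma_lp < 5):
            raise ValueError("sigma_0 and sigma_lp must lie in [0, 5)")
        if (np.abs(self.mu_x) >= 5).any():
            raise ValueError("mu_x must lie in (-5, 5)")
        if ((self.sigma_x < 0) | (self.sigma_x >= 5)).any():
            raise ValueError("sigma_x must lie in [0, 5)")
        if not -1 < self.rho_corr < 1:
            raise ValueError("rho_corr must lie in (-1, 1)")

    @property
    def mu_0(self) -> float:
        return float(logit(self.beta0_bar))

    @property
    def mu_lp(self) -> float:
        return float(logit(self.p_bar))


@dataclass
class SpeciesParams:
    """Species-level parameters (one entry per species, logit scale where noted)."""

    lp: np.ndarray                    # logit detection probability
    lpsi: np.ndarray | None = None    # null model: logit occupancy
    beta0: np.ndarray | None = None   # covariate model: occupancy intercept
    beta: np.ndarray | None = None    # covariate model: (K, X) slopes

    @property
    def p(self) -> np.ndarray:
        return expit(self.lp)

    @property
    def psi(self) -> np.ndarray:
        if self.lpsi is None:
            raise ValueError("psi is site-specific in the covariate model")
        return expit(self.lpsi)


@dataclass
class ModelSpec:
    """Which model variant to fit, with prior bounds and toggles."""

    variant: str = "null"                       # "null" | "covariate"
    covariates: list[str] = field(default_factory=list)
    sigma_max: float = 5.0                      # Uniform(0, sigma_max) sd hyperpriors
    mu_x_bound: float = 5.0                     # Uniform(-b, b) slope-mean hyperprior
    correlated: bool | None = None              # psi–p correlation; None → variant default
    link: str = "logit"

    def __post_init__(self):
        if self.variant not in ("null", "covariate"):
            raise ValueError(f"unknown model variant {self.variant!r}")
        if self.variant == "covariate" and not self.covariates:
            raise ValueError("covariate variant requires a covariate list")
        if self.variant == "null" and self.covariates:
            raise ValueError("null variant takes no covariates")
        if self.link != "logit":
            raise ValueError("only the logit link is supported")

    @property
    def use_correlation(self) -> bool:
        if self.correlated is None:
            return self.variant == "covariate"
        return bool(self.correlated)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Elementary densities
# ---------------------------------------------------------------------------

def _norm_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _logistic_logpdf(x):
    """Log-density of the standard logistic — the logit-scale image of Beta(1,1)."""
    return log_expit(x) + log_expit(-x)


def _bvn_logpdf(a, b, mean_a, mean_b, sd_a, sd_b, rho):
    """Bivariate normal log-density, elementwise over (a, b)."""
    za = (np.asarray(a, dtype=float) - mean_a) / sd_a
    zb = (np.asarray(b, dtype=float) - mean_b) / sd_b
    om = 1.0 - rho**2
    return (
        -_LOG_2PI
        - np.log(sd_a)
        - np.log(sd_b)
        - 0.5 * np.log(om)
        - (za**2 - 2.0 * rho * za * zb + zb**2) / (2.0 * om)
    )


# ---------------------------------------------------------------------------
# Model quantities
# ---------------------------------------------------------------------------

def occupancy_prob(beta_0k: float, beta_xk, cov_i) -> float:
    """Site occupancy probability psi_ik = logit⁻¹(beta0_k + Σ beta_xk·cov_i)."""
    beta_xk = np.atleast_1d(np.asarray(beta_xk, dtype=float))
    cov_i = np.atleast_1d(np.asarray(cov_i, dtype=float))
    if beta_xk.shape != cov_i.shape:
        raise ValueError(
            f"slope vector length {beta_xk.shape} != covariate vector length {cov_i.shape}"
        )
    return float(expit(beta_0k + float(beta_xk @ cov_i)))


def occupancy_logits(state: dict, spec: ModelSpec, x_sites: np.ndarray | None) -> np.ndarray:
    """Logit-scale occupancy, shape (K, I).

    ``x_sites`` is the (I, X) standardized covariate matrix for the
    covariate variant (ignored for the null variant, where a single column
    of the species logit is broadcast across sites).
    """
    if spec.variant == "null":
        n_sites = 1 if x_sites is None else x_sites.shape[0]
        return np.repeat(state["lpsi"][:, None], n_sites, axis=1)
    return state["beta0"][:, None] + state["beta"] @ x_sites.T


def site_marginal_loglik(y_history, psi: float, p: float, effort_mask=None) -> float:
    """Marginal log-likelihood of one species' detection history at one site.

    The latent occupancy state is summed out::

        log[ psi * prod_j p^y_j (1-p)^(1-y_j)  +  (1-psi) * 1{all y_j = 0} ]

    with the product over occasions that had effort.  Detections recorded in
    zero-effort occasions are input errors.
    """
    y = np.asarray(y_history, dtype=int)
    if effort_mask is None:
        effort_mask = np.ones_like(y, dtype=bool)
    effort_mask = np.asarray(effort_mask, dtype=bool)
    if (y[~effort_mask] != 0).any():
        raise ValueError("detection recorded in a zero-effort occasion")
    if not (0 < psi <= 1 and 0 < p < 1):
        raise ValueError("psi must lie in (0, 1] and p in (0, 1)")
    y = y[effort_mask]
    n_det = int(y.sum())
    n_occ = int(y.size)
    log_det = n_det * np.log(p) + (n_occ - n_det) * np.log1p(-p)
    if n_det > 0:
        return float(np.log(psi) + log_det)
    # both branches contribute when nothing was seen
    with np.errstate(divide="ignore"):  # psi = 1 → empty unoccupied branch
        return float(np.logaddexp(np.log(psi) + log_det, np.log1p(-psi)))


def log_prior_density(state: dict, spec: ModelSpec) -> float:
    """Joint log-density of species-level priors and community hyperpriors.

    Returns -inf outside any prior support (never raises for that).  Uniform
    hyperpriors contribute their normalizing constants so the value is a
    proper log-density, and the community means contribute the logistic
    density implied by their Beta(1,1) probability-scale priors.
    """
    sig_max = spec.sigma_max
    for name in (
        ("sigma_lpsi", "sigma_lp") if spec.variant == "null" else ("sigma_0", "sigma_lp")
    ):
        if not 0 < state[name] < sig_max:
            return -np.inf
    total = 0.0
    if spec.variant == "null":
        total += float(_logistic_logpdf(state["mu_lpsi"]))
        total += float(_logistic_logpdf(state["mu_lp"]))
        total -= 2.0 * np.log(sig_max)
        total += float(_norm_logpdf(state["lpsi"], state["mu_lpsi"], state["sigma_lpsi"]).sum())
        total += float(_norm_logpdf(state["lp"], state["mu_lp"], state["sigma_lp"]).sum())
        return total

    # covariate variant
    mu_x = np.atleast_1d(state["mu_x"])
    sigma_x = np.atleast_1d(state["sigma_x"])
    if (np.abs(mu_x) >= spec.mu_x_bound).any():
        return -np.inf
    if ((sigma_x <= 0) | (sigma_x >= sig_max)).any():
        return -np.inf
    total += float(_logistic_logpdf(state["mu_0"]))
    total += float(_logistic_logpdf(state["mu_lp"]))
    total -= 2.0 * np.log(sig_max)                       # sigma_0, sigma_lp
    total -= mu_x.size * np.log(2.0 * spec.mu_x_bound)   # mu_x ~ U(-b, b)
    total -= sigma_x.size * np.log(sig_max)              # sigma_x ~ U(0, 5)
    if spec.use_correlation:
        if not -1 < state["rho"] < 1:
            return -np.inf
        total -= np.log(2.0)                             # rho ~ U(-1, 1)
        total += float(
            _bvn_logpdf(
                state["beta0"], state["lp"],
                state["mu_0"], state["mu_lp"],
                state["sigma_0"], state["sigma_lp"], state["rho"],
            ).sum()
        )
    else:
        total += float(_norm_logpdf(state["beta0"], state["mu_0"], state["sigma_0"]).sum())
        total += float(_norm_logpdf(state["lp"], state["mu_lp"], state["sigma_lp"]).sum())
    total += float(_norm_logpdf(state["beta"], mu_x[None, :], sigma_x[None, :]).sum())
    return total


def complete_data_log_posterior(
    z: np.ndarray,
    state: dict,
    data,
    cov=None,
    spec: ModelSpec | None = None,
) -> float:
    """Joint log-density of (y, z, parameters) — the sampler's target.

    Sum of: detection terms log p(y | z, p), occupancy terms log p(z | psi),
    species-level priors and hyperpriors.  A z inconsistent with a detection
    (z = 0 where y = 1) yields -inf.
    """
    spec = spec or ModelSpec()
    z = np.asarray(z, dtype=int)
    y = data.y
    mask = data.effort_mask  # (I, J)
    if ((y == 1) & (z[:, :, None] == 0) & mask[None, :, :]).any():
        return -np.inf
    lp_prior = log_prior_density(state, spec)
    if not np.isfinite(lp_prior):
        return -np.inf
    p = expit(state["lp"])  # (K,)
    n_det = (y * mask[None, :, :]).sum(axis=2)     # (K, I)
    n_occ = mask.sum(axis=1)                       # (I,)
    det = z * (n_det * np.log(p)[:, None] + (n_occ[None, :] - n_det) * np.log1p(-p)[:, None])
    x_sites = cov.values() if cov is not None else None
    eta = occupancy_logits(state, spec, x_sites)   # (K, I) or (K, 1)
    occ = z * log_expit(eta) + (1 - z) * log_expit(-eta)
    return float(det.sum() + occ.sum() + lp_prior)
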