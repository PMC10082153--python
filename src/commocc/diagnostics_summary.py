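"""Convergence diagnostics and posterior summary tables.

Provides the classic (non-split) multi-chain Gelman–Rubin statistic, an
effective-sample-size estimate with Geyer's initial-positive-sequence
truncation, the iterate-until-converged driver, and the summary table with
columns mu, sd, LCI, md, UCI, Rhat, ESS, overlap0 and f — the
machine-readable twin of a community occupancy results table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc_engine import PosteriorDraws, SamplerConfig


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray, split: bool = False) -> float:
    """Gelman–Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_iter).  The classic multi-chain form is the
    default: with W the mean within-chain variance and B/n the variance of
    the chain means, Rhat = sqrt(((n-1)/n W + B/n) / W).  ``split=True``
    halves each chain first (the modern variant, more sensitive to
    within-chain trends).  Chains with zero within-chain variance everywhere
    have no defined Rhat; NaN is returned with a warning.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs a (n_chains >= 2, n_iter) array")
    if x.shape[1] < 10:
        raise ValueError("rhat needs at least 10 iterations per chain")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n = x.shape
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        warnings.warn("zero within-chain variance; Rhat undefined", stacklevel=2)
        return float("nan")
    B_over_n = x.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * W + B_over_n
    return float(math.sqrt(var_hat / W))


def ess(chains: np.ndarray) -> float:
    """Effective sample size, pooled across chains.

    ESS = N / (1 + 2 Σ ρ_t) with the autocorrelations averaged across
    chains and the sum truncated by Geyer's initial positive sequence:
    consecutive pairs (ρ_{2k}, ρ_{2k+1}) are added while their sum stays
    positive.  A constant chain has no defined ESS and returns NaN.
    """
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = x.shape
    if m * n < 100:
        raise ValueError("ess needs at least 100 total draws")
    if np.allclose(x.var(axis=1), 0):
        warnings.warn("constant chain; ESS undefined", stacklevel=2)
        return float("nan")
    acov = np.zeros(n)
    for row in x:
        acov += _autocov_fft(row)
    acov /= m
    if acov[0] == 0:
        warnings.warn("zero variance; ESS undefined", stacklevel=2)
        return float("nan")
    rho = acov / acov[0]
    # Geyer initial positive sequence: add (rho[2k-1] + rho[2k]) pairs
    # (lag 0 excluded) while each pair sum is positive.
    tail = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tail += pair
        t += 2
    denom = 1.0 + 2.0 * tail
    return float(m * n / max(denom, 1e-12))


def _autocov_fft(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def _summary_row(pooled: np.ndarray, by_chain: np.ndarray | None, ci_level: float) -> dict:
    alpha = (1.0 - ci_level) / 2.0
    lci, md, uci = np.quantile(pooled, [alpha, 0.5, 1.0 - alpha])
    mu = float(pooled.mean())
    sign_mu = np.sign(mu)
    f = float((np.sign(pooled) == sign_mu).mean()) if sign_mu != 0 else float("nan")
    row = {
        "mu": mu,
        "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        "lci": float(lci),
        "md": float(md),
        "uci": float(uci),
        "overlap0": int(lci <= 0.0 <= uci),
        "f": f,
    }
    if by_chain is not None and by_chain.shape[0] >= 2 and by_chain.shape[1] >= 10:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["rhat"] = rhat(by_chain)
            row["ess"] = ess(by_chain) if by_chain.size >= 100 else float("nan")
    else:
        row["rhat"] = float("nan")
        row["ess"] = float("nan")
    return row


def summarize(
    draws: PosteriorDraws | dict[str, np.ndarray],
    ci_level: float = 0.95,
    transforms: dict[str, tuple[str, callable]] | None = None,
) -> pd.DataFrame:
    """Posterior summary table: mu, sd, lci, md, uci, rhat, ess, overlap0, f.

    One row per parameter, quantiles by linear interpolation, 95% equal-tail
    credible intervals by default.  ``transforms`` adds derived rows: each
    entry maps a source parameter to (new_name, fn), summarizing fn(draws).
    """
    if isinstance(draws, PosteriorDraws):
        table = draws.draws
    else:
        table = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in draws.items()}
    if not table:
        raise ValueError("no draws to summarize")
    rows = {}
    for name, arr in table.items():
        rows[name] = _summary_row(arr.reshape(-1), arr, ci_level)
    for src, (new_name, fn) in (transforms or {}).items():
        arr = fn(table[src])
        rows[new_name] = _summary_row(np.asarray(arr).reshape(-1), np.asarray(arr), ci_level)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "parameter"
    return out[["mu", "sd", "lci", "md", "uci", "rhat", "ess", "overlap0", "f"]]


def community_table(draws: PosteriorDraws, ci_level: float = 0.95) -> pd.DataFrame:
    """Community-level summary on the probability scale.

    For the null variant: rows ``p`` and ``psi`` summarize the inverse-logit
    of the community mean hyperparameter draws (the community-average
    detection and occupancy probabilities).  For the covariate variant: row
    ``b0`` is the community occupancy intercept on the probability scale
    (its logit-scale twin is ``b0_logit``) and one row per covariate
    summarizes the community mean slope mu_x on the logit scale.
    """
    d = draws.draws
    if draws.spec.variant == "null":
        derived = {
            "p": expit(d["mu_lp"]),
            "psi": expit(d["mu_lpsi"]),
        }
    else:
        derived = {
            "b0": expit(d["mu_0"]),
            "b0_logit": d["mu_0"],
            "p": expit(d["mu_lp"]),
        }
        for c in draws.spec.covariates:
            derived[c] = d[f"mu_x[{c}]"]
    return summarize(derived, ci_level=ci_level)


def species_table(draws: PosteriorDraws, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-species probability-scale summaries (and slopes, if present).

    Null variant: ``p[sp]`` and ``psi[sp]`` rows on the probability scale.
    Covariate variant: ``p[sp]``, ``psi0[sp]`` (occupancy at average
    covariates) and ``beta[sp,cov]`` logit-scale effect rows — the
    caterpillar-plot data.
    """
    d = draws.draws
    derived: dict[str, np.ndarray] = {}
    for sp in draws.species_ids:
        derived[f"p[{sp}]"] = expit(d[f"lp[{sp}]"])
        if draws.spec.variant == "null":
            derived[f"psi[{sp}]"] = expit(d[f"lpsi[{sp}]"])
        else:
            derived[f"psi0[{sp}]"] = expit(d[f"beta0[{sp}]"])
            for c in draws.spec.covariates:
                derived[f"beta[{sp},{c}]"] = d[f"beta[{sp},{c}]"]
    return summarize(derived, ci_level=ci_level)


def effects_long_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-species covariate effects in long form (species, covariate, mu, lci, uci)."""
    if draws.spec.variant != "covariate":
        raise ValueError("effects table requires the covariate variant")
    rows = []
    for sp in draws.species_ids:
        for c in draws.spec.covariates:
            pooled = draws.pooled(f"beta[{sp},{c}]")
            lci, uci = np.quantile(pooled, [0.025, 0.975])
            rows.append(
                {"species": sp, "covariate": c, "mu": float(pooled.mean()),
                 "lci": float(lci), "uci": float(uci)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Iterate-until-converged driver
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    draws: PosteriorDraws
    converged: bool
    log: list[dict]


def max_rhat(draws: PosteriorDraws) -> tuple[float, str]:
    """Largest Rhat over all retained parameters, with the parameter name."""
    worst, worst_name = -np.inf, ""
    for name, arr in draws.draws.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = rhat(arr)
        if np.isnan(r):
            continue
        if r > worst:
            worst, worst_name = r, name
    return float(worst), worst_name


def converge_or_extend(
    fit,
    config: SamplerConfig,
    rhat_threshold: float = 1.05,
    max_rounds: int = 3,
) -> ConvergenceResult:
    """Fit, check Rhat, and double the chain length until convergence.

    ``fit`` is a callable mapping a SamplerConfig to PosteriorDraws and must
    be deterministic given the config's seed.  Each extension round doubles
    ``n_iter`` and derives a fresh seed from the master seed, so no round
    re-uses randomness.  Exhausting ``max_rounds`` returns the last fit
    flagged unconverged (never raises for non-convergence).
    """
    log: list[dict] = []
    current = config
    draws = None
    for round_idx in range(1, max_rounds + 1):
        draws = fit(current)
        worst, worst_name = max_rhat(draws)
        entry = {
            "round": round_idx,
            "n_iter": current.n_iter,
            "seed": current.master_seed,
            "max_rhat": worst,
            "worst_parameter": worst_name,
        }
        log.append(entry)
        if worst < rhat_threshold:
            return ConvergenceResult(draws=draws, converged=True, log=log)
        fresh_seed = int(
            np.random.SeedSequence([config.master_seed, round_idx]).generate_state(1)[0]
            % (2**31)
        )
        current = replace(current, n_iter=current.n_iter * 2, master_seed=fresh_seed)
    return ConvergenceResult(draws=draws, converged=False, log=log)
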