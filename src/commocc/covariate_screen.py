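"""Pre-model covariate screening: correlation, collinearity, standardization.

Site covariates entering the occupancy model are screened for pairwise
Pearson correlation (flag |r| ≥ 0.7) and collinearity via variance inflation
factors (flag VIF ≥ 10).  Screening is advisory — it produces a report and
warnings, not a hard stop.  Covariates are z-scored before fitting so that
the Uniform(−5, 5) hyperpriors on logit-scale slopes span a sensible effect
range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camtrap_data import COVARIATE_COLUMNS, SiteCovariates


@dataclass
class ScreenReport:
    """Pairwise correlations and per-covariate VIFs with screening flags."""

    pearson: pd.DataFrame  # columns cov_a, cov_b, r, flagged
    vif: pd.DataFrame      # columns covariate, vif, flagged

    @property
    def any_flagged(self) -> bool:
        return bool(self.pearson["flagged"].any() or self.vif["flagged"].any())


def _check_variance(x: np.ndarray, names: list[str]) -> None:
    sds = x.std(axis=0, ddof=1)
    for name, sd in zip(names, sds):
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} has zero variance")


def pearson_screen(covariates: SiteCovariates, threshold: float = 0.7) -> pd.DataFrame:
    """All pairwise Pearson correlations; pairs with |r| ≥ threshold are flagged."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    x = covariates.values()
    names = covariates.names
    if x.shape[0] < 3:
        raise ValueError("need at least 3 sites for correlation screening")
    _check_variance(x, names)
    r = np.corrcoef(x, rowvar=False)
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            rows.append(
                {
                    "cov_a": names[a],
                    "cov_b": names[b],
                    "r": r[a, b],
                    "flagged": bool(abs(r[a, b]) >= threshold),
                }
            )
    return pd.DataFrame(rows)


def vif_screen(covariates: SiteCovariates, threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1 / (1 − R²_j).

    R²_j comes from the least-squares regression (with intercept) of
    covariate j on the others.  Perfect collinearity reports an infinite VIF
    and is flagged.
    """
    x = covariates.values()
    names = covariates.names
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need more sites than covariates + 1 for VIF screening")
    _check_variance(x, names)
    rows = []
    for j in range(p):
        yj = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": names[j], "vif": vif, "flagged": bool(vif >= threshold)})
    return pd.DataFrame(rows)


def screen(
    covariates: SiteCovariates,
    r_threshold: float = 0.7,
    vif_threshold: float = 10.0,
) -> ScreenReport:
    """Run both screens; emit a warning (not an error) for flagged covariates."""
    report = ScreenReport(
        pearson=pearson_screen(covariates, r_threshold),
        vif=vif_screen(covariates, vif_threshold),
    )
    if report.any_flagged:
        flagged_pairs = report.pearson.loc[report.pearson["flagged"], ["cov_a", "cov_b"]]
        flagged_vifs = report.vif.loc[report.vif["flagged"], "covariate"]
        warnings.warn(
            "covariate screening flagged correlated/collinear covariates: "
            f"pairs={flagged_pairs.to_records(index=False).tolist()}, "
            f"vif={list(flagged_vifs)}",
            stacklevel=2,
        )
    return report


def standardize(covariates: SiteCovariates) -> SiteCovariates:
    """Z-score each covariate column (denominator n − 1).

    The transform parameters are stored on the result so fitted slopes can be
    back-transformed to raw covariate units.  Idempotent up to floating point.
    """
    x = covariates.values()
    _check_variance(x, covariates.names)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    z = (x - means) / sds
    table = covariates.table.copy()
    table[COVARIATE_COLUMNS] = z
    if covariates.standardized:
        # compose with the original transform so back-transformation still works
        means = covariates.means.to_numpy() + covariates.sds.to_numpy() * means
        sds = covariates.sds.to_numpy() * sds
    return SiteCovariates(
        table=table,
        standardized=True,
        means=pd.Series(means, index=COVARIATE_COLUMNS),
        sds=pd.Series(sds, index=COVARIATE_COLUMNS),
    )
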