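"""Family/link diagnostics for the conditional-cost GLM.

The battery runs four checks on a fitted second-part model simultaneously:

1. **Modified Park test** — regress squared raw residuals on the log fitted
   mean with a log-link quasi-likelihood GLM.  The slope λ is the implied
   power of the variance function Var(y|x) ∝ μ^λ: λ ≈ 0 suggests a Gaussian
   family, ≈ 1 Poisson-like, ≈ 2 gamma, ≈ 3 inverse Gaussian.
2. **Pregibon link test** — refit the family with the linear predictor and
   its square as the only regressors; a significant squared term indicates a
   misspecified link.
3. **Modified Hosmer–Lemeshow test** — regress raw residuals on decile groups
   of the fitted values; the joint F-test that all decile means are zero
   detects systematic lack of fit.
4. **Pearson correlation test** — zero-correlation test between raw residuals
   and the linear predictor.

The recommendation maps the rounded Park λ to a family and keeps the log link
unless the Pregibon test rejects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_FAMILY_BY_LAMBDA = {0: "gaussian", 1: "poisson", 2: "gamma", 3: "inverse_gaussian"}


@dataclass
class FamilyLinkReport:
    park_lambda: float
    park_se: float
    park_family: str
    pregibon_stat: float
    pregibon_p: float
    hl_stat: float
    hl_p: float
    pearson_r: float
    pearson_p: float
    recommended_family: str
    recommended_link: str

    def summary(self) -> str:
        return (
            f"modified Park: lambda={self.park_lambda:.3f} (SE {self.park_se:.3f})"
            f" -> {self.park_family}\n"
            f"Pregibon link: z={self.pregibon_stat:.3f}, p={self.pregibon_p:.4f}\n"
            f"modified Hosmer-Lemeshow: F={self.hl_stat:.3f}, p={self.hl_p:.4f}\n"
            f"Pearson residual-index correlation: r={self.pearson_r:.4f},"
            f" p={self.pearson_p:.4f}\n"
            f"recommendation: family={self.recommended_family}, link={self.recommended_link}"
        )


def modified_park(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Variance-power estimate: GLM of (y−μ̂)² on log μ̂ with log link.

    Quasi-likelihood estimation with a log link (Poisson working variance) is
    the standard implementation; returns (λ, SE(λ)).
    """
    res2 = (y - mu) ** 2
    X = np.column_stack([np.ones_like(mu), np.log(mu)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer "counts" are intended
        fit = sm.GLM(res2, X, family=sm.families.Poisson()).fit(scale="X2")
    return float(fit.params[1]), float(fit.bse[1])


def pregibon_link(y: np.ndarray, eta: np.ndarray) -> tuple[float, float]:
    """Link test: z-statistic and p-value for η² in a refit on (η, η²)."""
    X = np.column_stack([np.ones_like(eta), eta, eta**2])
    fit = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit(
        scale="X2"
    )
    z = float(fit.params[2] / fit.bse[2])
    return z, float(2 * stats.norm.sf(abs(z)))


def modified_hosmer_lemeshow(
    y: np.ndarray, mu: np.ndarray, groups: int = 10
) -> tuple[float, float]:
    """F-test that mean raw residuals are zero across fitted-value deciles."""
    if len(np.unique(mu)) < groups:
        raise ValueError(
            f"fewer than {groups} distinct fitted values; decile groups undefined"
        )
    resid = y - mu
    decile = pd.qcut(pd.Series(mu).rank(method="first"), groups, labels=False)
    D = pd.get_dummies(decile).to_numpy(dtype=float)
    fit = sm.OLS(resid, D).fit()
    ftest = fit.f_test(np.eye(groups))
    return float(ftest.fvalue), float(ftest.pvalue)


def pearson_correlation_test(y: np.ndarray, mu: np.ndarray, eta: np.ndarray) -> tuple[float, float]:
    """Zero-correlation test between raw residuals and the linear predictor."""
    r, p = stats.pearsonr(y - mu, eta)
    return float(r), float(p)


def diagnose_family_link(X: pd.DataFrame, y: np.ndarray, fit) -> FamilyLinkReport:
    """Run the four-test battery on a fitted gamma/log second part.

    ``fit`` must expose ``fitted`` (μ̂) and ``linear_predictor`` (η̂) over the
    same rows as ``y``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(fit.fitted, dtype=float)
    eta = np.asarray(fit.linear_predictor, dtype=float)

    lam, lam_se = modified_park(y, mu)
    preg_z, preg_p = pregibon_link(y, eta)
    hl_f, hl_p = modified_hosmer_lemeshow(y, mu)
    r, r_p = pearson_correlation_test(y, mu, eta)

    nearest = int(np.clip(round(lam), 0, 3))
    family = _FAMILY_BY_LAMBDA[nearest]
    link = "log" if preg_p > 0.05 else "log (link test rejects: re-examine)"
    return FamilyLinkReport(
        park_lambda=lam,
        park_se=lam_se,
        park_family=family,
        pregibon_stat=preg_z,
        pregibon_p=preg_p,
        hl_stat=hl_f,
        hl_p=hl_p,
        pearson_r=r,
        pearson_p=r_p,
        recommended_family=family,
        recommended_link=link,
    )
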