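"""Two-part model for semicontinuous annual healthcare costs.

Part one is a probit regression for the probability of any resource use in a
patient-year; part two is a gamma GLM with log link for the cost conditional
on use, fitted on the positive-cost rows.  The unconditional mean annual cost
per patient is the product Φ(xβ̂)·exp(xγ̂) averaged over the sample's covariate
distribution (recycled prediction).  The second-part specification is compared
against OLS on costs and OLS on log costs by AIC, and checked with a battery
of four family/link diagnostics.  Uncertainty for the mean comes from a
nonparametric bootstrap that resamples patients (preserving within-patient
clustering across follow-up years); a delta-method alternative is available.

Sensitivity refits estimate the mean separately for patients alive and dead at
the end of five years, with the mortality terms removed from the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignSpec, build_design

__all__ = [
    "ProbitFit",
    "GammaGLMFit",
    "ComparatorAICs",
    "TwoPartFit",
    "SeparationError",
    "fit_probit",
    "fit_glm_gamma_log",
    "fit_comparators",
    "fit_two_part",
    "predict_mean_cost",
    "bootstrap_ci",
    "fit_sensitivity",
]


class SeparationError(RuntimeError):
    """Perfect separation: the probit likelihood has no finite maximiser."""


@dataclass
class ProbitFit:
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool
    n: int

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.llf

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se},
            index=self.params.index,
        )


@dataclass
class GammaGLMFit:
    params: pd.Series
    cov: pd.DataFrame
    shape: float
    llf: float
    aic: float
    n: int
    fitted: np.ndarray = field(repr=False, default=None)
    linear_predictor: np.ndarray = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se},
            index=self.params.index,
        )


@dataclass
class ComparatorAICs:
    """AICs of the second-part comparators.

    ``log_ols_log_scale`` is the Gaussian AIC of OLS on log costs computed on
    the log scale; ``log_ols_jacobian`` adds the change-of-variables term
    (2·Σ log y) so it is comparable with AICs on the cost scale.  Cross-model
    selection uses the Jacobian-adjusted value.
    """

    ols: float
    log_ols_log_scale: float
    log_ols_jacobian: float
    gamma_glm: float

    def best(self) -> str:
        cands = {
            "ols": self.ols,
            "log_ols": self.log_ols_jacobian,
            "gamma_glm": self.gamma_glm,
        }
        return min(cands, key=cands.get)


@dataclass
class TwoPartFit:
    #: None when every row has positive cost (degenerate first part == 1)
    probit: ProbitFit | None
    gamma: GammaGLMFit
    comparators: ComparatorAICs | None
    diagnostics: object | None
    spec: DesignSpec
    columns: list[str]
    n_part1: int
    n_part2: int
    #: declared design columns with no observations (empty factor levels)
    #: excluded from the fit
    dropped_columns: tuple[str, ...] = ()


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop columns that are linearly dependent on earlier ones (pivoted QR)."""
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return X, ()
    from scipy import linalg

    _, _, piv = linalg.qr(A, mode="economic", pivoting=True)
    keep = sorted(piv[:rank])
    dropped = tuple(X.columns[i] for i in range(A.shape[1]) if i not in keep)
    return X.iloc[:, keep], dropped


def _drop_quasi_separated(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop 0/1 indicator columns whose support has a constant binary outcome.

    Such columns (sparse factor levels in small strata) have no finite probit
    coefficient; their likelihood contribution is maximised at ±∞ and Newton
    scoring breaks down.
    """
    y = np.asarray(y, dtype=float)
    dropped: list[str] = []
    while True:
        bad = None
        for c in X.columns:
            col = X[c].to_numpy()
            if c == "intercept" or not set(np.unique(col)) <= {0.0, 1.0}:
                continue
            sub = y[col == 1]
            if len(sub) and (sub.min() == sub.max()):
                bad = c
                break
        if bad is None:
            return X, tuple(dropped)
        X = X.drop(columns=[bad])
        dropped.append(bad)


def _validate_design(X: pd.DataFrame) -> None:
    zero = [c for c in X.columns if (X[c] == 0).all()]
    if zero:
        raise ValueError(f"design column(s) constant zero: {zero}")


def fit_probit(X: pd.DataFrame, y, maxiter: int = 100, tol: float = 1e-10) -> ProbitFit:
    """Probit fit by Newton scoring; covariance from the observed information.

    Raises :class:`SeparationError` on (quasi-)perfect separation and
    ``ValueError`` on degenerate outcomes or rank-deficient designs.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("any_use outcome is constant; probit is undefined")
    _validate_design(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        res = sm.Probit(y, X.to_numpy()).fit(
            method="newton", maxiter=maxiter, tol=tol, disp=0, warn_convergence=False
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        if isinstance(e, np.linalg.LinAlgError):
            raise ValueError(f"singular/rank-deficient probit design: {e}") from e
        raise SeparationError(str(e)) from e
    eta = X.to_numpy() @ res.params
    if np.abs(eta[(y == 1)]).size and (
        np.all(eta[y == 1] > 5) and np.all(eta[y == 0] < -5)
    ):
        raise SeparationError("fitted index separates outcomes completely")
    if not np.all(np.isfinite(res.params)):
        raise SeparationError("non-finite probit estimates")
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return ProbitFit(
        params=params,
        cov=cov,
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n=len(y),
    )


def fit_glm_gamma_log(
    X: pd.DataFrame, y, maxiter: int = 200, tol: float = 1e-10
) -> GammaGLMFit:
    """Gamma GLM with log link by IRLS, on strictly positive outcomes.

    The gamma shape is a nuisance parameter estimated by moments from the
    Pearson residuals (shape = 1 / Pearson dispersion); the log-likelihood and
    AIC are evaluated at that shape, with the shape counted as an estimated
    parameter: AIC = 2(p+1) − 2·loglik.
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("second-part outcome must be strictly positive")
    _validate_design(X)
    if y.max() - y.min() < 1e-12:
        # constant outcome: the perfect fit is intercept = log(c), rest 0
        params = pd.Series(0.0, index=X.columns)
        params.iloc[0] = float(np.log(y[0]))
        shape = 1e12
        llf = float(np.sum(stats.gamma.logpdf(y, a=shape, scale=y / shape)))
        return GammaGLMFit(
            params=params,
            cov=pd.DataFrame(0.0, index=X.columns, columns=X.columns),
            shape=shape,
            llf=llf,
            aic=2 * (X.shape[1] + 1) - 2 * llf,
            n=len(y),
            fitted=y.copy(),
            linear_predictor=np.full(len(y), np.log(y[0])),
        )
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=maxiter, tol=tol, scale="X2")
    if not res.converged:
        raise RuntimeError(f"gamma GLM IRLS failed to converge in {maxiter} iterations")
    mu = np.asarray(res.fittedvalues)
    # Pearson chi^2 / df_resid; floored so degenerate (constant-cost) inputs
    # keep a finite shape
    dispersion = max(float(res.scale), 1e-12)
    shape = 1.0 / dispersion
    llf = float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu / shape)))
    k = X.shape[1] + 1  # coefficients + shape
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return GammaGLMFit(
        params=params,
        cov=cov,
        shape=shape,
        llf=llf,
        aic=2 * k - 2 * llf,
        n=len(y),
        fitted=mu,
        linear_predictor=np.asarray(X.to_numpy() @ res.params),
    )


def _cluster_sandwich(score_rows: np.ndarray, hessian: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Sandwich covariance A^-1 B A^-1 with scores summed within clusters."""
    g = pd.DataFrame(score_rows).groupby(groups).sum().to_numpy()
    n_g = g.shape[0]
    meat = g.T @ g * (n_g / max(n_g - 1, 1))
    bread = np.linalg.inv(hessian)
    return bread @ meat @ bread


def _cluster_sandwich_probit(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    eta = X @ beta
    p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    phi = stats.norm.pdf(eta)
    score_rows = ((y - p) * phi / (p * (1 - p)))[:, None] * X
    w = phi**2 / (p * (1 - p))  # expected information weights
    hessian = (X * w[:, None]).T @ X
    return _cluster_sandwich(score_rows, hessian, groups)


def _cluster_sandwich_gamma(
    X: np.ndarray, y: np.ndarray, gamma: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    mu = np.exp(X @ gamma)
    # quasi-score of the gamma/log GLM (up to the dispersion factor, which
    # cancels in the sandwich)
    score_rows = ((y - mu) / mu)[:, None] * X
    hessian = X.T @ X  # gamma/log working information, dispersion cancelled
    return _cluster_sandwich(score_rows, hessian, groups)


def fit_comparators(X: pd.DataFrame, y, gamma_aic: float | None = None) -> ComparatorAICs:
    """Gaussian AICs for OLS on costs and OLS on log costs.

    The residual variance counts as an estimated parameter (k = p + 1).  The
    log-OLS AIC is reported both on the log scale and with the Jacobian
    adjustment 2·Σ log y that maps its likelihood back to the cost scale.
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("comparators require strictly positive outcomes")
    k = X.shape[1] + 1
    Xa = X.to_numpy()
    ols = sm.OLS(y, Xa).fit()
    aic_ols = 2 * k - 2 * float(ols.llf)
    logy = np.log(y)
    lols = sm.OLS(logy, Xa).fit()
    aic_log = 2 * k - 2 * float(lols.llf)
    aic_log_jac = aic_log + 2 * float(np.sum(logy))
    return ComparatorAICs(
        ols=aic_ols,
        log_ols_log_scale=aic_log,
        log_ols_jacobian=aic_log_jac,
        gamma_glm=float("nan") if gamma_aic is None else gamma_aic,
    )


def fit_two_part(
    panel: pd.DataFrame,
    spec: DesignSpec | None = None,
    compare: bool = True,
    diagnose: bool = False,
    drop_empty_levels: bool = True,
    cluster_robust: bool = False,
) -> TwoPartFit:
    """Fit both model parts on a costed patient-year panel.

    Factor levels declared in the design but absent from the panel produce
    all-zero indicator columns; with ``drop_empty_levels`` (default) they —
    and any aliased (linearly dependent) columns, e.g. an interaction level
    coinciding with a sparse main effect — are excluded from the fit and
    recorded in ``dropped_columns`` instead of raising.
    """
    spec = spec or DesignSpec()
    X, any_use, total = build_design(panel, spec)
    dropped: tuple[str, ...] = ()
    if drop_empty_levels:
        empty = [c for c in X.columns if (X[c] == 0).all()]
        if empty:
            dropped = tuple(empty)
            X = X.drop(columns=empty)
        if any_use.min() != any_use.max():
            X, quasi = _drop_quasi_separated(X, any_use.to_numpy())
            X, aliased = _drop_aliased(X)
            dropped = dropped + quasi + aliased
        else:
            X, aliased = _drop_aliased(X)
            dropped = dropped + aliased
    if any_use.min() == any_use.max() == 1:
        # every patient-year has positive cost: the model collapses to its
        # second part and the probability part is identically one
        probit = None
    else:
        probit = fit_probit(X, any_use)
    pos = total > 0
    gamma = fit_glm_gamma_log(X.loc[pos], total[pos])
    if cluster_robust:
        # repeated follow-up years per patient are dependent; replace the
        # model-based covariances with sandwich estimates clustered on patient
        groups = pd.factorize(panel["patient_id"])[0]
        if probit is not None:
            probit.cov = pd.DataFrame(
                _cluster_sandwich_probit(
                    X.to_numpy(), any_use.to_numpy(dtype=float),
                    probit.params.to_numpy(), groups,
                ),
                index=X.columns, columns=X.columns,
            )
        gamma.cov = pd.DataFrame(
            _cluster_sandwich_gamma(
                X.loc[pos].to_numpy(), total[pos].to_numpy(),
                gamma.params.to_numpy(), groups[pos.to_numpy()],
            ),
            index=X.columns, columns=X.columns,
        )
    comparators = None
    if compare:
        comparators = fit_comparators(X.loc[pos], total[pos], gamma_aic=gamma.aic)
    diag = None
    if diagnose:
        from .diagnostics import diagnose_family_link

        diag = diagnose_family_link(X.loc[pos], total[pos].to_numpy(), gamma)
    return TwoPartFit(
        probit=probit,
        gamma=gamma,
        comparators=comparators,
        diagnostics=diag,
        spec=spec,
        columns=list(X.columns),
        n_part1=len(panel),
        n_part2=int(pos.sum()),
        dropped_columns=dropped,
    )


def predict_mean_cost(fit: TwoPartFit, X: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-row expected annual cost Φ(xβ̂)·exp(xγ̂) and its grand mean.

    The grand mean over the estimation sample's rows is the recycled
    prediction of mean annual cost per patient.
    """
    if list(X.columns) != fit.columns:
        raise ValueError("design columns do not match the fitted model")
    Xa = X.to_numpy()
    p_use = (
        np.ones(len(Xa))
        if fit.probit is None
        else stats.norm.cdf(Xa @ fit.probit.params.to_numpy())
    )
    per_row = p_use * np.exp(Xa @ fit.gamma.params.to_numpy())
    return per_row, float(per_row.mean())


def mean_annual_cost(panel: pd.DataFrame, fit: TwoPartFit) -> float:
    """Recycled-prediction mean annual cost over the panel."""
    X, _, _ = build_design(panel, fit.spec)
    if fit.dropped_columns:
        X = X.drop(columns=[c for c in fit.dropped_columns if c in X.columns])
    return predict_mean_cost(fit, X)[1]


SECTOR_COLUMNS = ("cost_inpatient", "cost_outpatient", "cost_prescribing", "cost_care_home")


def _fit_probit_raw(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Probit coefficients on raw arrays (bootstrap fast path).

    Returns None when every row is a user (probability part identically 1).
    """
    if y.min() == y.max() == 1:
        return None
    if y.min() == y.max() or (X == 0).all(axis=0).any():
        raise ValueError("degenerate bootstrap replicate")
    res = sm.Probit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0,
                              warn_convergence=False)
    if not np.all(np.isfinite(res.params)):
        raise SeparationError("non-finite probit estimates")
    return np.asarray(res.params)


def _fit_gamma_raw(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gamma/log GLM coefficients on raw arrays (bootstrap fast path)."""
    if len(y) == 0 or (X == 0).all(axis=0).any():
        raise ValueError("degenerate bootstrap replicate")
    if y.max() - y.min() < 1e-12:
        out = np.zeros(X.shape[1])
        out[0] = np.log(y[0])
        return out
    res = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit(
        maxiter=200, tol=1e-10
    )
    if not res.converged:
        raise RuntimeError("gamma GLM did not converge")
    return np.asarray(res.params)


def bootstrap_ci(
    panel: pd.DataFrame,
    spec: DesignSpec | None = None,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    max_attempts: int = 3,
) -> dict:
    """Percentile bootstrap CI for the recycled-prediction mean annual cost.

    Resamples *patients* with replacement (preserving within-patient
    clustering across follow-up years), refits both parts, and recomputes the
    recycled mean on each replicate.  Empirical sector means are bootstrapped
    alongside.  Replicates whose refit fails (e.g. separation in a small
    resample) are redrawn up to ``max_attempts`` times, then recorded as
    failures.  Deterministic given ``seed``; the point estimate comes from the
    original sample and is unaffected by ``B``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    spec = spec or DesignSpec()
    if spec.year_center is None and "year" in spec.blocks:
        # freeze the centring so resampled designs align with the original
        import dataclasses

        spec = dataclasses.replace(spec, year_center=int(panel["admission_year"].min()))
    fit = fit_two_part(panel, spec, compare=False)
    point = mean_annual_cost(panel, fit)
    sectors = [c for c in SECTOR_COLUMNS if c in panel.columns]
    sector_point = {c: float(panel[c].mean()) for c in sectors}

    # encode once; replicates resample design rows by patient
    X, y_any, total = build_design(panel, spec)
    Xa = X.to_numpy()
    ya = y_any.to_numpy().astype(float)
    ta = total.to_numpy()
    sector_a = {c: panel[c].to_numpy(dtype=float) for c in sectors}
    codes, _ = pd.factorize(panel["patient_id"], sort=False)
    n_pat = codes.max() + 1
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(n_pat + 1))
    row_groups = [order[starts[i] : starts[i + 1]] for i in range(n_pat)]

    rng = np.random.default_rng([int(seed) % (2**31), 7])
    means = np.empty(B)
    sector_means = {c: np.empty(B) for c in sectors}
    failures = 0
    for b in range(B):
        for attempt in range(max_attempts):
            chosen = rng.integers(0, n_pat, size=n_pat)
            rows = np.concatenate([row_groups[p] for p in chosen])
            Xb, yb, tb = Xa[rows], ya[rows], ta[rows]
            try:
                beta = _fit_probit_raw(Xb, yb)
                pos = tb > 0
                gamma = _fit_gamma_raw(Xb[pos], tb[pos])
                p_use = 1.0 if beta is None else stats.norm.cdf(Xb @ beta)
                means[b] = float((p_use * np.exp(Xb @ gamma)).mean())
                break
            except (SeparationError, ValueError, RuntimeError, np.linalg.LinAlgError):
                failures += 1
        else:
            means[b] = np.nan
        for c in sectors:
            sector_means[c][b] = sector_a[c][rows].mean()

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ok = np.isfinite(means)
    result = {
        "mean_annual_cost": {
            "point": point,
            "lower": float(np.percentile(means[ok], lo)),
            "upper": float(np.percentile(means[ok], hi)),
        },
        "refit_failures": failures,
        "B": B,
    }
    for c in sectors:
        result[c] = {
            "point": sector_point[c],
            "lower": float(np.percentile(sector_means[c], lo)),
            "upper": float(np.percentile(sector_means[c], hi)),
        }
    return result


def delta_method_ci(panel: pd.DataFrame, fit: TwoPartFit, alpha: float = 0.05) -> dict:
    """Delta-method CI for the recycled mean (model-based alternative).

    Treats the two parts as independent (they are estimated on overlapping
    rows, so this is approximate) and propagates coefficient covariance
    through the gradient of the mean.
    """
    X, _, _ = build_design(panel, fit.spec)
    Xa = X.to_numpy()
    beta = fit.probit.params.to_numpy()
    gamma = fit.gamma.params.to_numpy()
    xb = Xa @ beta
    eg = np.exp(Xa @ gamma)
    per_row = stats.norm.cdf(xb) * eg
    point = per_row.mean()
    # gradients of the grand mean w.r.t. beta and gamma
    g_beta = (stats.norm.pdf(xb) * eg) @ Xa / len(Xa)
    g_gamma = per_row @ Xa / len(Xa)
    var = float(
        g_beta @ fit.probit.cov.to_numpy() @ g_beta
        + g_gamma @ fit.gamma.cov.to_numpy() @ g_gamma
    )
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(var)
    return {"point": float(point), "lower": float(point - z * se), "upper": float(point + z * se)}


def fit_sensitivity(
    panel: pd.DataFrame, status: str, spec: DesignSpec | None = None
) -> tuple[TwoPartFit, float]:
    """Refit on the alive or dead stratum, without mortality adjustment.

    ``status`` is "alive" or "dead" (5-year vital status).  The design drops
    the mortality main effect and its SIMD interaction.  Returns the stratum
    fit and its recycled-prediction mean annual cost.
    """
    if status not in ("alive", "dead"):
        raise ValueError(f"status must be 'alive' or 'dead', got {status!r}")
    want_dead = status == "dead"
    sub = panel[panel["died_within_5y"].astype(bool) == want_dead]
    if sub.empty:
        raise ValueError(f"empty stratum: no {status} patients in the panel")
    import dataclasses

    base = spec or DesignSpec()
    strat_spec = dataclasses.replace(
        base,
        include_mortality=False,
        mortality_simd_interaction=False,
        year_center=base.year_center
        if (base.year_center is not None or "year" not in base.blocks)
        else int(panel["admission_year"].min()),
    )
    fit = fit_two_part(sub, strat_spec, compare=False)
    return fit, mean_annual_cost(sub, fit)
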