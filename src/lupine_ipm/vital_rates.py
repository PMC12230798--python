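"""Estimation of size-dependent vital rates from individual and field records.

Follows the analysis protocol of the greenhouse study: logistic (logit-link
maximum-likelihood) regressions of survival and flowering on log size at t,
ordinary least squares for growth (log size at t+1) and flowering-shoot
number, and sample mean/variance for the recruit-size distribution. Survival
and flowering-shoot number are, by default, fitted once on the data pooled
across origins and treatments and copied into every cell's parameter set;
growth, flowering and recruit size are cell-specific. Only linear size
relationships are allowed.

Seed output per flowering shoot comes from field records: per plant, mean
seeds per pod (three sampled pods) times pods per inflorescence; plant values
are averaged per population and population means averaged per region.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from .params import (
    CELLS,
    GaussianRate,
    LinearRate,
    LogisticRate,
    RecruitSize,
    VitalRateParams,
)


class SeparationError(RuntimeError):
    """A logistic vital-rate fit is degenerate or perfectly separated."""

    def __init__(self, rate: str, detail: str):
        super().__init__(f"logistic fit for '{rate}' is degenerate: {detail}")
        self.rate = rate


class InsufficientDataError(ValueError):
    """A stratum lacks the data needed to fit a vital rate."""


# Convergence settings for the logistic fits (IRLS).
_LOGIT_TOL = 1e-10
_LOGIT_MAXITER = 100


def _check_sizes(x: np.ndarray, label: str) -> None:
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise InsufficientDataError(
            f"{label}: need >= 2 distinct size_t values, got {np.unique(x).size}"
        )


def _fit_logistic(x: np.ndarray, y: np.ndarray, rate: str):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size == 0:
        raise InsufficientDataError(f"{rate}: no observations")
    if np.all(y == y[0]):
        raise SeparationError(rate, f"all outcomes equal {int(y[0])}")
    _check_sizes(x, rate)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=_LOGIT_MAXITER, tol=_LOGIT_TOL
        )
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        raise SeparationError(rate, "coefficients diverged (perfect separation)")
    mu = res.fittedvalues
    if np.all((mu > 1 - 1e-10) == y.astype(bool)) and np.all((mu < 1e-10) == ~y.astype(bool)):
        raise SeparationError(rate, "fitted probabilities are all 0/1")
    se = np.asarray(res.bse, dtype=float)
    return LogisticRate(intercept=float(params[0]), slope=float(params[1])), (
        float(se[0]),
        float(se[1]),
    )


def _fit_ols(x: np.ndarray, y: np.ndarray, label: str):
    """OLS of y on x; returns (intercept, slope, unbiased residual variance, SEs)."""
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = np.asarray(x, float)[mask], np.asarray(y, float)[mask]
    if x.size < 2:
        raise InsufficientDataError(f"{label}: need >= 2 observations, got {x.size}")
    _check_sizes(x, label)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_var = float(res.mse_resid) if x.size > 2 else 0.0
    # With exactly 2 points the fit is exact; mse_resid divides by n - k = 0.
    if x.size == 2:
        resid_var = 0.0
    se = np.asarray(res.bse, dtype=float)
    return float(res.params[0]), float(res.params[1]), resid_var, (float(se[0]), float(se[1]))


def _fit_truncated_gaussian(x: np.ndarray, y: np.ndarray, label: str):
    """ML fit of y ~ N(a + b x, s^2) left-truncated at 0.

    Flowering-shoot counts are non-negative by construction; maximum
    likelihood under the zero-truncated Gaussian recovers the latent linear
    mean without the downward-truncation bias of plain least squares (and
    coincides with OLS when the truncation probability is negligible). Falls
    back to the OLS solution if the optimizer fails.
    """
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = np.asarray(x, float)[mask], np.asarray(y, float)[mask]
    a0, b0, v0, se0 = _fit_ols(x, y, label)
    if v0 <= 0:
        return a0, b0, se0

    def nll(theta):
        a, b, log_s = theta
        s = np.exp(log_s)
        mu = a + b * x
        return -np.sum(norm.logpdf(y, loc=mu, scale=s) - norm.logcdf(mu / s))

    start = np.array([a0, b0, 0.5 * math.log(v0)])
    opt = minimize(nll, start, method="BFGS", options={"maxiter": 500})
    if not np.all(np.isfinite(opt.x)):
        return a0, b0, se0
    try:
        hess = approx_hess(opt.x, nll)
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov)[:2], 0.0))
        if not np.all(np.isfinite(se)) or np.any(se == 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se = np.asarray(se0)
    return float(opt.x[0]), float(opt.x[1]), (float(se[0]), float(se[1]))


def _fit_shoots(x: np.ndarray, y: np.ndarray, label: str, model: str):
    if model == "truncated":
        a, b, se = _fit_truncated_gaussian(x, y, label)
    elif model == "ols":
        a, b, _, se = _fit_ols(x, y, label)
    else:
        raise ValueError(f"shoot_model must be 'truncated' or 'ols', got {model!r}")
    return LinearRate(intercept=a, slope=b), se


def fit_vital_rates(
    records: pd.DataFrame,
    pool_survival_and_shoots: bool = True,
    seeds_per_shoot: Optional[Mapping[str, float]] = None,
    e: float = 0.122,
    e_sb: float = 0.122,
    s_sb: float = 0.977,
    shoot_model: str = "truncated",
    return_se: bool = False,
) -> dict:
    """Fit all vital rates; returns {(origin, treatment): VitalRateParams}.

    Survival and flowering-shoot number are fitted on the pooled records when
    ``pool_survival_and_shoots`` is set (the default, mirroring the published
    analysis) and the identical coefficients are copied into every cell.
    ``seeds_per_shoot`` maps origin to the regional seed constant; when absent
    the published constants are used. ``shoot_model`` selects the flowering
    shoot estimator: ``"truncated"`` (zero-truncated Gaussian ML, the default
    — shoot counts are non-negative) or ``"ols"``. With ``return_se`` the
    result is ``(params_by_cell, se_by_cell)`` where the second mapping holds
    estimated standard errors keyed by dotted component names.
    """
    if seeds_per_shoot is None:
        seeds_per_shoot = {o: canonical_constants()["seeds_per_shoot"][o]
                           for o in records["origin"].unique()}

    cells = sorted(
        records[["origin", "treatment"]].drop_duplicates().itertuples(index=False, name=None)
    )

    pooled_survival = pooled_shoots = None
    if pool_survival_and_shoots:
        pooled_survival = _fit_logistic(
            records["size_t"].to_numpy(), records["survived"].to_numpy(), "survival (pooled)"
        )
        fl = records[records["flowered"] == 1]
        pooled_shoots = _fit_shoots(
            fl["size_t"].to_numpy(), fl["n_shoots"].to_numpy(), "shoots (pooled)", shoot_model
        )

    out, ses = {}, {}
    for origin, treatment in cells:
        cell = records[(records["origin"] == origin) & (records["treatment"] == treatment)]
        label = f"{origin}/{treatment}"
        if len(cell) == 0:
            raise InsufficientDataError(f"{label}: no records")
        _check_sizes(cell["size_t"].to_numpy(), label)

        if pool_survival_and_shoots:
            (survival, se_s), (shoots, se_f1) = pooled_survival, pooled_shoots
        else:
            survival, se_s = _fit_logistic(
                cell["size_t"].to_numpy(), cell["survived"].to_numpy(), f"survival ({label})"
            )
            fl = cell[cell["flowered"] == 1]
            shoots, se_f1 = _fit_shoots(
                fl["size_t"].to_numpy(), fl["n_shoots"].to_numpy(),
                f"shoots ({label})", shoot_model,
            )

        surv = cell[cell["survived"] == 1]
        a_g, b_g, var_g, se_g = _fit_ols(
            surv["size_t"].to_numpy(), surv["size_t1"].to_numpy(), f"growth ({label})"
        )
        flowering, se_p = _fit_logistic(
            surv["size_t"].to_numpy(), surv["flowered"].to_numpy(), f"flowering ({label})"
        )
        sizes = cell["size_t"].to_numpy(dtype=float)
        recruit = RecruitSize(mean=float(np.mean(sizes)), variance=float(np.var(sizes, ddof=1)))

        out[(origin, treatment)] = VitalRateParams(
            survival=survival,
            growth=GaussianRate(intercept=a_g, slope=b_g, variance=var_g),
            flowering=flowering,
            shoots=shoots,
            recruit_size=recruit,
            e=e,
            e_sb=e_sb,
            s_sb=s_sb,
            seeds_per_shoot=float(seeds_per_shoot[origin]),
        )
        ses[(origin, treatment)] = {
            "survival.intercept": se_s[0],
            "survival.slope": se_s[1],
            "growth.intercept": se_g[0],
            "growth.slope": se_g[1],
            "flowering.intercept": se_p[0],
            "flowering.slope": se_p[1],
            "shoots.intercept": se_f1[0],
            "shoots.slope": se_f1[1],
            "recruit_size.mean": float(np.std(sizes, ddof=1) / np.sqrt(sizes.size)),
        }
    if return_se:
        return out, ses
    return out


def estimate_seed_constant(field: pd.DataFrame) -> float:
    """Regional seeds-per-flowering-shoot from field fecundity records.

    Per plant: mean seeds per pod (over its three sampled pods) x pods per
    inflorescence. Plant values are averaged within populations, and the
    population means averaged to a single regional constant.
    """
    if field is None or len(field) == 0:
        raise InsufficientDataError("field fecundity records are empty")
    seeds = field[["seeds_pod_1", "seeds_pod_2", "seeds_pod_3"]].to_numpy(dtype=float)
    per_plant = seeds.mean(axis=1) * field["pods_per_inflorescence"].to_numpy(dtype=float)
    per_population = (
        pd.Series(per_plant, index=field["population"].to_numpy()).groupby(level=0).mean()
    )
    return float(per_population.mean())


def _load_table() -> dict:
    with resources.files("lupine_ipm.data").joinpath("table2.yaml").open() as fh:
        return yaml.safe_load(fh)


def canonical_constants() -> dict:
    """The published life-cycle constants and regional seed numbers."""
    table = _load_table()
    return {"seeds_per_shoot": table["seeds_per_shoot"], **table["constants"]}


def canonical_params(origin: str, treatment: str) -> VitalRateParams:
    """Published vital-rate estimates for one origin x treatment cell."""
    table = _load_table()
    try:
        cell = table["cells"][origin][treatment]
    except KeyError:
        raise KeyError(
            f"unknown cell ({origin!r}, {treatment!r}); valid cells: {list(CELLS)}"
        ) from None
    return VitalRateParams(
        survival=LogisticRate(**table["pooled"]["survival"]),
        growth=GaussianRate(**cell["growth"]),
        flowering=LogisticRate(**cell["flowering"]),
        shoots=LinearRate(**table["pooled"]["shoots"]),
        recruit_size=RecruitSize(**cell["recruit_size"]),
        e=float(table["constants"]["e"]),
        e_sb=float(table["constants"]["e_sb"]),
        s_sb=float(table["constants"]["s_sb"]),
        seeds_per_shoot=float(table["seeds_per_shoot"][origin]),
    )


def canonical_table() -> dict:
    """All four published parameter sets keyed by (origin, treatment)."""
    return {(o, t): canonical_params(o, t) for o, t in CELLS}
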