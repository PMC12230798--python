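"""Asymptotic growth rate, bootstrap confidence intervals and sensitivities.

The asymptotic population growth rate lambda is the leading positive
eigenvalue of the discretized projection matrix, computed by power iteration
and cross-checked against a full eigen-decomposition. Confidence intervals are
percentile bootstrap over resampled individuals (within origin x treatment)
and field plants (within population). Sensitivities are brute-force
one-at-a-time: each parameter component is reduced by 1% of its value
(multiplicative, sign-preserving), the kernel rebuilt, and the absolute
proportional change |lambda' - lambda| / lambda recorded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .kernel import IPMConfig, build_kernel, default_size_limits
from .params import VitalRateParams
from .vital_rates import (
    InsufficientDataError,
    SeparationError,
    estimate_seed_constant,
    fit_vital_rates,
)

#: Parameter components perturbed by the sensitivity analysis (intercepts and
#: slopes separately, plus the recruit-size mean and the four constants; the
#: growth and recruit-size variances are excluded by default).
SENSITIVITY_COMPONENTS = (
    "survival.intercept",
    "survival.slope",
    "flowering.intercept",
    "flowering.slope",
    "growth.intercept",
    "growth.slope",
    "shoots.intercept",
    "shoots.slope",
    "recruit_size.mean",
    "seeds_per_shoot",
    "e",
    "s_sb",
    "e_sb",
)


@dataclass
class LambdaResult:
    """Point estimate of lambda with a percentile bootstrap CI."""

    origin: str
    treatment: str
    lam: float
    ci_low: float
    ci_high: float
    n_boot: int
    rng_seed: int
    n_redraws: int = 0

    def __post_init__(self):
        if not self.ci_low <= self.ci_high:
            raise ValueError(f"ci_low {self.ci_low} > ci_high {self.ci_high}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_lambda(
    A: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    cross_check: bool = True,
    cross_check_tol: float = 1e-8,
) -> float:
    """Dominant eigenvalue modulus of a non-negative matrix by power iteration.

    Raises on non-convergence (reporting the iteration count and residual) and
    on disagreement with the full eigen-decomposition beyond
    ``cross_check_tol`` relative.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    if np.any(A < 0):
        raise ValueError("matrix contains negative entries")

    n = A.shape[0]
    v = np.full(n, 1.0 / n)
    lam_prev = np.inf
    lam = 0.0
    for it in range(1, max_iter + 1):
        w = A @ v
        lam = float(np.linalg.norm(w, 1))
        if lam == 0.0:
            break  # nilpotent direction; dominant eigenvalue is 0
        v = w / lam
        if abs(lam - lam_prev) <= tol * max(lam, 1e-300):
            break
        lam_prev = lam
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {abs(lam - lam_prev):.3e})"
        )

    if cross_check:
        lam_eig = float(np.max(np.abs(scipy.linalg.eigvals(A))))
        if abs(lam - lam_eig) > cross_check_tol * max(1.0, lam_eig):
            raise RuntimeError(
                f"power iteration ({lam!r}) and eigen-decomposition ({lam_eig!r}) disagree"
            )
    return lam


def lambda_from_params(params: VitalRateParams, config: IPMConfig) -> float:
    """Convenience: build the kernel and return its dominant eigenvalue."""
    return compute_lambda(build_kernel(params, config).matrix)


def sensitivity_analysis(
    params: VitalRateParams,
    config: IPMConfig,
    components: Sequence[str] = SENSITIVITY_COMPONENTS,
    reduction: float = 0.01,
    include_growth_variance: bool = False,
) -> pd.DataFrame:
    """One-at-a-time proportional sensitivity of lambda.

    Each listed component c is set to (1 - reduction) * c (sign-preserving;
    a zero-valued component therefore yields sensitivity 0), the kernel is
    rebuilt from scratch with the size limits held at their baseline values,
    and |lambda' - lambda| / lambda is recorded as an absolute value.
    """
    components = list(components)
    if include_growth_variance:
        components.append("growth.variance")
    if config.L is None or config.U is None:
        L, U = default_size_limits({"cell": params}, config)
        config = dataclasses.replace(config, L=L, U=U)
    base = lambda_from_params(params, config)
    rows = []
    for comp in components:
        current = dict(params.flat_items())[comp]
        perturbed = params.replace_component(comp, (1.0 - reduction) * current)
        lam = lambda_from_params(perturbed, config)
        rows.append({"component": comp, "sensitivity": abs(lam - base) / base})
    return pd.DataFrame(rows).set_index("component")


def bootstrap_lambda(
    records: pd.DataFrame,
    field_by_origin: Mapping[str, pd.DataFrame],
    config: IPMConfig,
    n_boot: int = 1000,
    rng_seed: int = 0,
    pool_survival_and_shoots: bool = True,
    resample: bool = True,
    max_redraw_fraction: float = 0.2,
    e: float = 0.122,
    e_sb: float = 0.122,
    s_sb: float = 0.977,
) -> dict:
    """Percentile bootstrap CI of lambda per origin x treatment cell.

    Each replicate resamples individuals with replacement within every
    origin x treatment stratum and field plants within every population,
    refits all vital rates, rebuilds the kernels on the size limits resolved
    from the point-estimate data, and recomputes lambda. The CI is the central
    95% percentile interval over replicates. The literature constants e, e_sb
    and s_sb are never resampled. Replicates whose fit degenerates (e.g.
    separation) are redrawn; more than ``max_redraw_fraction`` redraws is an
    error. Deterministic given ``rng_seed``; ``resample=False`` reuses the full
    data in every replicate (identity resample), collapsing the CI onto the
    point estimate.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")

    def fit_all(recs: pd.DataFrame, fields: Mapping[str, pd.DataFrame]) -> dict:
        seeds = {origin: estimate_seed_constant(df) for origin, df in fields.items()}
        return fit_vital_rates(
            recs,
            pool_survival_and_shoots=pool_survival_and_shoots,
            seeds_per_shoot=seeds,
            e=e,
            e_sb=e_sb,
            s_sb=s_sb,
        )

    point_params = fit_all(records, field_by_origin)
    if config.L is None or config.U is None:
        sizes = np.concatenate(
            [
                records["size_t"].dropna().to_numpy(float),
                records["size_t1"].dropna().to_numpy(float),
            ]
        )
        from .kernel import resolve_size_limits

        L, U = resolve_size_limits(sizes, config)
        config = dataclasses.replace(config, L=L, U=U)
    point_lambda = {c: lambda_from_params(p, config) for c, p in point_params.items()}

    rng = np.random.default_rng(rng_seed)
    strata = {
        cell: grp.reset_index(drop=True)
        for cell, grp in records.groupby(["origin", "treatment"], sort=True)
    }
    field_strata = {
        origin: {pop: grp.reset_index(drop=True) for pop, grp in df.groupby("population", sort=True)}
        for origin, df in sorted(field_by_origin.items())
    }

    def one_resample():
        recs = pd.concat(
            [grp.iloc[rng.integers(0, len(grp), len(grp))] for _, grp in sorted(strata.items())],
            ignore_index=True,
        )
        fields = {
            origin: pd.concat(
                [g.iloc[rng.integers(0, len(g), len(g))] for _, g in sorted(pops.items())],
                ignore_index=True,
            )
            for origin, pops in field_strata.items()
        }
        return recs, fields

    draws = {cell: [] for cell in point_params}
    n_redraws = 0
    max_redraws = max(1, int(np.ceil(max_redraw_fraction * n_boot)))
    done = 0
    while done < n_boot:
        try:
            if resample:
                recs, fields = one_resample()
                rep = fit_all(recs, fields)
            else:
                rep = point_params
            rep_lambda = {c: lambda_from_params(p, config) for c, p in rep.items()}
        except (SeparationError, InsufficientDataError):
            n_redraws += 1
            if n_redraws > max_redraws:
                raise RuntimeError(
                    f"bootstrap exceeded {max_redraws} redraws "
                    f"({n_redraws} degenerate replicates out of {done} completed)"
                )
            continue
        for cell, lam in rep_lambda.items():
            draws[cell].append(lam)
        done += 1

    results = {}
    for cell, lam in point_lambda.items():
        arr = np.asarray(draws[cell])
        lo, hi = np.percentile(arr, [2.5, 97.5])
        results[cell] = LambdaResult(
            origin=cell[0],
            treatment=cell[1],
            lam=lam,
            ci_low=float(lo),
            ci_high=float(hi),
            n_boot=n_boot,
            rng_seed=rng_seed,
            n_redraws=n_redraws,
        )
    return results
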