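"""Poisson age-period-cohort model with the Intrinsic Estimator.

The APC model writes the expected death count in cell (i, j) as

    E[D_ij] = N_ij * exp(mu + alpha_i + beta_j + gamma_k),   k = A - i + j,

with person-years N_ij as the exposure offset and sum-to-zero (effect)
coded age, period and cohort blocks.  Because cohort = period - age
exactly, the design matrix X loses one rank: its kernel is spanned by a
single unit vector B0 whose entries are linear in category index
within each block.  Any least-squares/ML solution is identified only
up to multiples of B0 — the classical APC identification problem.

The Intrinsic Estimator (IE) picks the unique solution orthogonal to
B0, i.e. the minimum-norm solution.  It is computed here by the
principal-components route: project the design onto the orthogonal
complement of B0 (the non-null right singular vectors of X), fit an
ordinary Poisson GLM with offset on that full-rank reduced design by
IRLS, then map coefficients and covariance back.  Second differences
of the effect curves are estimable functions — identical under any
resolution of the identification problem — and are exposed for
verification against constrained fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .lexis import CohortBin, PeriodBin, RateTable, cohort_index

#: Relative singular-value threshold separating the null direction.
_KERNEL_RTOL = 1e-8


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class APCDesign:
    """Effect-coded APC design with its one-dimensional null space.

    ``matrix`` is (A*P) x m with m = 1 + (A-1) + (P-1) + (C-1) columns
    (intercept, age, period, cohort blocks; the last category of each
    block is omitted and reconstructed as the negative sum).  Row order
    is age-major over the grid.
    """

    matrix: np.ndarray
    column_index: dict[str, range]
    null_vector: np.ndarray
    dims: tuple[int, int, int]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


def _effect_row(category: int, n_categories: int) -> np.ndarray:
    """Sum-to-zero coding row for a 1-based category (last omitted)."""
    row = np.zeros(n_categories - 1)
    if category == n_categories:
        row[:] = -1.0
    else:
        row[category - 1] = 1.0
    return row


def build_design(A: int, P: int) -> APCDesign:
    """Build the effect-coded APC design for an A x P grid."""
    if A < 2 or P < 2:
        raise ValueError("need at least 2 age groups and 2 periods")
    C = A + P - 1
    m = 1 + (A - 1) + (P - 1) + (C - 1)
    rows = []
    for i in range(1, A + 1):
        for j in range(1, P + 1):
            k = cohort_index(i, j, A)
            rows.append(
                np.concatenate(
                    [
                        [1.0],
                        _effect_row(i, A),
                        _effect_row(j, P),
                        _effect_row(k, C),
                    ]
                )
            )
    X = np.array(rows)
    column_index = {
        "intercept": range(0, 1),
        "age": range(1, A),
        "period": range(A, A + P - 1),
        "cohort": range(A + P - 1, m),
    }
    b0 = _kernel_basis(X)
    return APCDesign(matrix=X, column_index=column_index, null_vector=b0, dims=(A, P, C))


def _kernel_basis(X: np.ndarray) -> np.ndarray:
    """Unit-norm basis of ker(X); errors unless the kernel is 1-D.

    Sign is fixed so the first age-block entry (index 1) is positive.
    """
    _, s, Vt = np.linalg.svd(X, full_matrices=True)
    m = X.shape[1]
    n_null = m - len(s) + int(np.sum(s < _KERNEL_RTOL * s[0]))
    if n_null != 1:
        raise ValueError(f"design kernel has dimension {n_null}, expected 1")
    b0 = Vt[-1]
    if b0[1] < 0:
        b0 = -b0
    return b0 / np.linalg.norm(b0)


def null_vector(design: APCDesign) -> np.ndarray:
    """The design's unit null vector B0 (X @ B0 = 0)."""
    return design.null_vector


@dataclass
class FitStats:
    """Goodness-of-fit summary for one APC-IE fit.

    ``aic`` is per-observation: (-2 logLik + 2 rank) / n_obs.  ``bic``
    is the deviance-based form deviance - (n_obs - rank) * ln(n_obs).
    ``model_rank`` counts the IE's m - 1 = 2A + 2P - 4 effective
    parameters.
    """

    deviance: float
    aic: float
    bic: float
    n_obs: int
    model_rank: int


@dataclass
class IEFit:
    """Intrinsic-Estimator coefficients, SEs and fit statistics."""

    intercept: float
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    intercept_se: float
    age_se: np.ndarray
    period_se: np.ndarray
    cohort_se: np.ndarray
    covariance: np.ndarray
    fitted_deaths: np.ndarray
    stats: FitStats | None
    design: APCDesign
    table: RateTable

    @property
    def se(self) -> dict[str, np.ndarray]:
        return {
            "intercept": np.array([self.intercept_se]),
            "age": self.age_se,
            "period": self.period_se,
            "cohort": self.cohort_se,
        }


def _expand_block(b: np.ndarray, cov: np.ndarray, idx: range):
    """Full effect vector and SEs for one block under effect coding.

    The omitted last category equals the negative sum of the others;
    its variance is 1' Cov_block 1.
    """
    coefs = b[list(idx)]
    full = np.concatenate([coefs, [-coefs.sum()]])
    block_cov = cov[np.ix_(list(idx), list(idx))]
    se = np.sqrt(np.concatenate([np.diag(block_cov), [block_cov.sum()]]))
    return full, se


def poisson_deviance(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Residual deviance 2 * sum[d log(d / mu) - (d - mu)], 0 log 0 = 0."""
    d = np.asarray(observed, dtype=float)
    mu = np.asarray(fitted, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * np.sum(term - (d - mu)))


def fit_ie(
    table: RateTable, tol: float = 1e-10, maxiter: int = 100
) -> IEFit:
    """Fit the Poisson APC model by the Intrinsic Estimator.

    The design columns are projected onto the orthogonal complement of
    B0 (orthonormal basis from the non-null right singular vectors),
    the reduced full-rank Poisson GLM with log person-years offset is
    fitted by IRLS to a deviance change below ``tol``, and coefficients
    and covariance are mapped back through the basis — the minimum-norm
    (intrinsic) solution.
    """
    A, P = table.shape
    design = build_design(A, P)
    X = design.matrix
    _, _, Vt = np.linalg.svd(X, full_matrices=True)
    # all right singular vectors except the null direction
    U = Vt[:-1].T  # m x (m-1), orthonormal, spans complement of B0
    Xr = X @ U

    y = table.deaths.reshape(-1)
    offset = np.log(table.person_years.reshape(-1))
    model = sm.GLM(y, Xr, family=sm.families.Poisson(), offset=offset)
    res = model.fit(method="IRLS", maxiter=maxiter, tol=tol)
    trace = list(res.fit_history.get("deviance", []))
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(last deviance {trace[-1] if trace else float('nan')})",
            trace,
        )

    b = U @ res.params
    cov = U @ res.cov_params() @ U.T

    alpha, alpha_se = _expand_block(b, cov, design.column_index["age"])
    beta, beta_se = _expand_block(b, cov, design.column_index["period"])
    gamma, gamma_se = _expand_block(b, cov, design.column_index["cohort"])
    mu = float(b[0])
    mu_se = float(np.sqrt(cov[0, 0]))

    fitted = np.asarray(res.mu).reshape(A, P)
    fit = IEFit(
        intercept=mu,
        age_effects=alpha,
        period_effects=beta,
        cohort_effects=gamma,
        intercept_se=mu_se,
        age_se=alpha_se,
        period_se=beta_se,
        cohort_se=gamma_se,
        covariance=cov,
        fitted_deaths=fitted,
        stats=None,  # set below
        design=design,
        table=table,
    )
    fit.stats = fit_stats(fit, table)
    return fit


def fit_stats(fit: IEFit, table: RateTable) -> FitStats:
    """Deviance, per-observation AIC and deviance-based BIC."""
    A, P = table.shape
    n = A * P
    rank = 2 * A + 2 * P - 4
    d = table.deaths.reshape(-1)
    mu = fit.fitted_deaths.reshape(-1)
    deviance = poisson_deviance(d, mu)
    loglik = float(np.sum(d * np.log(mu) - mu - gammaln(d + 1)))
    aic = (-2.0 * loglik + 2.0 * rank) / n
    bic = deviance - (n - rank) * np.log(n)
    return FitStats(deviance=deviance, aic=aic, bic=float(bic), n_obs=n, model_rank=rank)


def estimable_second_differences(fit: IEFit) -> dict[str, np.ndarray]:
    """Second differences of each effect block.

    Delta^2 v_i = v_{i+1} - 2 v_i + v_{i-1}: invariant to the level and
    linear-trend indeterminacy, hence identical for any resolution of
    the identification problem.  Blocks shorter than 3 yield an empty
    sequence.
    """
    out = {}
    for name, v in (
        ("age", fit.age_effects),
        ("period", fit.period_effects),
        ("cohort", fit.cohort_effects),
    ):
        out[name] = np.diff(v, n=2) if len(v) >= 3 else np.array([])
    return out


def display_subset(
    fit: IEFit,
    periods: list[PeriodBin] | None = None,
    cohorts: list[CohortBin] | None = None,
) -> pd.DataFrame:
    """Coefficient/SE rows for a subset of categories, without refitting.

    Long-series fits are conventionally displayed on a common window;
    the values shown are the full-fit coefficients, partially
    displayed.  Unknown labels raise KeyError.
    """
    table = fit.table
    all_periods = {pb: j for j, pb in enumerate(table.period_bins)}
    all_cohorts = {cb: k for k, cb in enumerate(table.cohort_bins())}
    periods = list(all_periods) if periods is None else periods
    cohorts = list(all_cohorts) if cohorts is None else cohorts

    rows = []
    for i, ag in enumerate(table.age_groups):
        rows.append(("age", ag.label, fit.age_effects[i], fit.age_se[i]))
    for pb in periods:
        if pb not in all_periods:
            raise KeyError(f"period {pb.label} not in fit")
        j = all_periods[pb]
        rows.append(("period", pb.label, fit.period_effects[j], fit.period_se[j]))
    for cb in cohorts:
        if cb not in all_cohorts:
            raise KeyError(f"cohort {cb.label} not in fit")
        kk = all_cohorts[cb]
        rows.append(("cohort", cb.label, fit.cohort_effects[kk], fit.cohort_se[kk]))
    return pd.DataFrame(rows, columns=["block", "category", "coef", "se"])
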