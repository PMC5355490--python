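"""Centile derivation, curve smoothing, and distribution fitting.

Percentiles 1–99 are read directly off the empirical cumulative distribution
of each age-group pmf — with millions of observations per group there is no
need to posit a parametric family first.  Parametric alternatives (Gaussian,
logistic, and the LMS Box-Cox-normal model of growth-chart practice) and
quantile regression are provided for comparison: their sup-norm discrepancy
against the empirical CDF quantifies how far each family is from the data.

Centile curves are smoothed over age with LOWESS per percentile level, then
re-monotonized across levels so smoothed curves never cross.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.optimize import isotonic_regression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ages import enumerate_age_groups
from .distributions import (
    VALUE_BINS,
    AgeGroupDistribution,
    DegenerateDistributionError,
    pmf_mean_sd,
)

logger = logging.getLogger(__name__)

PERCENTILE_LEVELS = tuple(range(1, 100))

_GROUPS_BY_LABEL = {g.label: g for g in enumerate_age_groups()}


@dataclass(frozen=True)
class EmpiricalCDF:
    """Cumulative probabilities over the occupied integer support."""

    variable: str
    age_group: str
    support: np.ndarray  # occupied integer values, ascending
    cumulative: np.ndarray  # same length; non-decreasing; ends at 1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ValueError("cumulative probabilities must be non-decreasing")
        if abs(self.cumulative[-1] - 1.0) > 1e-9:
            raise ValueError("CDF must reach 1 on its support")


def empirical_cdf(dist: AgeGroupDistribution) -> EmpiricalCDF:
    """Prefix sums of the pmf over its occupied support."""
    occupied = dist.pmf > 0
    return EmpiricalCDF(
        variable=dist.variable,
        age_group=dist.age_group,
        support=VALUE_BINS[occupied].astype(float),
        cumulative=np.cumsum(dist.pmf[occupied]),
    )


def percentile_from_cdf(cdf: EmpiricalCDF, level: float) -> float:
    """Value at percentile ``level`` (1..99) by linear interpolation.

    The target probability q = level/100 is bracketed between consecutive
    support values and interpolated linearly on the CDF.  Levels at or below
    the first cumulative mass — including every level of a point mass — map
    to the smallest support value.
    """
    if not (1 <= level <= 99):
        raise ValueError(f"percentile level must lie in 1..99, got {level}")
    q = level / 100.0
    F = cdf.cumulative
    v = cdf.support
    if q <= F[0]:
        return float(v[0])
    j = int(np.searchsorted(F, q, side="left"))  # first index with F[j] >= q
    f_lo, f_hi = F[j - 1], F[j]
    if f_hi == f_lo:  # flat region: smallest bracketing value
        return float(v[j - 1])
    t = (q - f_lo) / (f_hi - f_lo)
    return float(v[j - 1] + t * (v[j] - v[j - 1]))


@dataclass
class CentileTable:
    """Percentile levels 1..99 by age group for one variable.

    ``data`` is a DataFrame indexed by age-group label (in age order), with
    columns ``p1`` .. ``p99``; rows are non-decreasing across levels.
    """

    variable: str
    data: pd.DataFrame
    smoothed: bool = False

    def __post_init__(self) -> None:
        expected = [f"p{p}" for p in PERCENTILE_LEVELS]
        if list(self.data.columns) != expected:
            raise ValueError("centile table must have columns p1..p99")

    @property
    def levels(self) -> tuple[int, ...]:
        return PERCENTILE_LEVELS


def build_centile_table(
    distributions: Iterable[AgeGroupDistribution],
    levels: Sequence[int] = PERCENTILE_LEVELS,
) -> CentileTable:
    """Raw centile table: one row per age group, ordered by age."""
    dists = list(distributions)
    if not dists:
        raise ValueError("no group distributions supplied")
    variables = {d.variable for d in dists}
    if len(variables) != 1:
        raise ValueError(f"mixed variables: {sorted(variables)}")
    dists.sort(key=lambda d: _GROUPS_BY_LABEL[d.age_group].midpoint_days)
    rows = {}
    for d in dists:
        cdf = empirical_cdf(d)
        rows[d.age_group] = [percentile_from_cdf(cdf, p) for p in levels]
    data = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{p}" for p in levels]
    )
    return CentileTable(variable=variables.pop(), data=data, smoothed=False)


def _enforce_row_monotone(data: pd.DataFrame) -> pd.DataFrame:
    """Project each row onto non-decreasing order across levels (isotonic)."""
    out = data.copy()
    for label in out.index:
        row = out.loc[label].to_numpy(dtype=float)
        if np.any(np.diff(row) < 0):
            out.loc[label] = isotonic_regression(row).x
    return out


def smooth_centiles_over_age(
    table: CentileTable, span: float = 0.3
) -> CentileTable:
    """LOWESS each percentile level over age-group midpoints.

    The age coordinate is the group midpoint in days; the coarse (0–18 y)
    groups widen roughly geometrically, so their midpoints are log-scaled
    before smoothing while day-level groups use linear age.  After
    smoothing, within-row monotonicity across levels is restored by
    isotonic adjustment so centile curves cannot cross.

    Tables with fewer than 3 rows are returned unchanged (with a warning):
    a local linear fit needs at least 3 points.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must lie in (0, 1], got {span}")
    if len(table.data) < 3:
        logger.warning(
            "centile table has %d rows; need >= 3 for age smoothing — returning as-is",
            len(table.data),
        )
        return CentileTable(
            variable=table.variable, data=table.data.copy(), smoothed=True
        )
    groups = [_GROUPS_BY_LABEL[label] for label in table.data.index]
    kinds = {g.kind for g in groups}
    if len(kinds) != 1:
        raise ValueError("cannot smooth a table mixing day-level and coarse groups")
    x = np.array([g.midpoint_days for g in groups])
    if kinds.pop() == "coarse":
        x = np.log(x)
    frac = max(span, min(1.0, 3.0 / x.size))
    smoothed = {}
    for col in table.data.columns:
        y = table.data[col].to_numpy(dtype=float)
        # it=0: plain local-linear fits. Residual-based robustness iterations
        # degenerate on noiseless centile rows (median |residual| ~ 0 makes
        # every reweight collapse) and would disable smoothing entirely.
        smoothed[col] = lowess(y, x, frac=frac, it=0, return_sorted=False)
    data = pd.DataFrame(smoothed, index=table.data.index)
    data = _enforce_row_monotone(data)
    return CentileTable(variable=table.variable, data=data, smoothed=True)


# ---------------------------------------------------------------------------
# Parametric fits
# ---------------------------------------------------------------------------

FitFamily = Literal["gaussian", "logistic", "lms"]


@dataclass
class FitResult:
    """Maximum-likelihood fit of one family to a group pmf.

    ``parameters`` holds (mean, sd) for gaussian, (location, scale) for
    logistic, and (L, M, S) for the LMS Box-Cox-normal model, where L is the
    Box-Cox power, M the median, and S the coefficient of variation.
    ``discrepancy`` is the sup-norm distance between fitted and empirical
    CDFs over the integer support.
    """

    family: FitFamily
    parameters: dict[str, float]
    discrepancy: float = field(default=float("nan"))

    def cdf(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        p = self.parameters
        if self.family == "gaussian":
            return stats.norm.cdf(values, loc=p["mean"], scale=p["sd"])
        if self.family == "logistic":
            return stats.logistic.cdf(values, loc=p["location"], scale=p["scale"])
        if self.family == "lms":
            return stats.norm.cdf(_lms_z(values, p["L"], p["M"], p["S"]))
        raise ValueError(f"unknown family {self.family!r}")

    def quantile(self, q: float) -> float:
        p = self.parameters
        if self.family == "gaussian":
            return float(stats.norm.ppf(q, loc=p["mean"], scale=p["sd"]))
        if self.family == "logistic":
            return float(stats.logistic.ppf(q, loc=p["location"], scale=p["scale"]))
        if self.family == "lms":
            z = stats.norm.ppf(q)
            L, M, S = p["L"], p["M"], p["S"]
            if abs(L) < 1e-8:
                return float(M * np.exp(S * z))
            return float(M * np.power(1.0 + L * S * z, 1.0 / L))
        raise ValueError(f"unknown family {self.family!r}")


def _lms_z(x: np.ndarray, L: float, M: float, S: float) -> np.ndarray:
    """Box-Cox z-score: ((x/M)^L - 1) / (L*S), or ln(x/M)/S at L = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(L) < 1e-8:
            return np.log(x / M) / S
        return (np.power(x / M, L) - 1.0) / (L * S)


def _lms_profile(pmf: np.ndarray, support: np.ndarray, L: float):
    """Closed-form (M, S) and log-likelihood at a fixed Box-Cox power L.

    At fixed L, x^L is normal with mean M^L and sd |L| S M^L, so weighted
    moments of x^L give M and S directly; the profile log-likelihood adds
    the Jacobian term (L-1) E[ln x].
    """
    w = pmf
    lx = np.log(support)
    if abs(L) < 1e-8:
        m = float(w @ lx)
        s2 = float(w @ (lx - m) ** 2)
        M = float(np.exp(m))
        S = float(np.sqrt(s2))
        z = (lx - m) / S
        ll = float(w @ (stats.norm.logpdf(z) - np.log(S) - lx))
        return M, S, ll
    y = np.power(support, L)
    my = float(w @ y)
    sy = float(np.sqrt(w @ (y - my) ** 2))
    if my <= 0 or sy <= 0:
        return float("nan"), float("nan"), -np.inf
    M = float(np.power(my, 1.0 / L))
    S = sy / (abs(L) * my)
    z = (y - my) / sy
    # log pdf = log phi(z) + ln|L| + (L-1) ln x - ln(sd_y); sd_y = |L| S M^L
    ll = float(
        w @ (stats.norm.logpdf(z) + np.log(abs(L)) + (L - 1.0) * lx - np.log(sy))
    )
    return M, S, ll


def fit_parametric(
    dist: AgeGroupDistribution,
    family: FitFamily,
    l_bounds: tuple[float, float] = (-3.0, 3.0),
    tol: float = 1e-8,
) -> FitResult:
    """Weighted maximum-likelihood fit of ``family`` to a group pmf.

    The pmf is treated as weighted data on its integer support.  LMS is fit
    by profile likelihood over L (bounded), with closed-form M and S at each
    candidate L.
    """
    mean, sd = pmf_mean_sd(dist.pmf)
    if sd <= 0:
        raise DegenerateDistributionError("cannot fit a parametric family to a point mass")
    occupied = dist.pmf > 0
    support = VALUE_BINS[occupied].astype(float)
    w = dist.pmf[occupied]

    if family == "gaussian":
        params = {"mean": mean, "sd": sd}
    elif family == "logistic":
        def nll(theta):
            loc, log_s = theta
            return -float(w @ stats.logistic.logpdf(support, loc=loc, scale=np.exp(log_s)))

        x0 = np.array([mean, np.log(sd * np.sqrt(3.0) / np.pi)])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if not res.success:
            raise RuntimeError(f"logistic MLE failed to converge: {res.message}")
        params = {"location": float(res.x[0]), "scale": float(np.exp(res.x[1]))}
    elif family == "lms":
        res = optimize.minimize_scalar(
            lambda L: -_lms_profile(w, support, L)[2],
            bounds=l_bounds,
            method="bounded",
            options={"xatol": tol},
        )
        L = float(res.x)
        M, S, ll = _lms_profile(w, support, L)
        if not np.isfinite(ll):
            raise RuntimeError(
                f"LMS profile likelihood is degenerate at L={L:.4f} "
                f"(iterations: {res.nfev}, message: {getattr(res, 'message', '')})"
            )
        params = {"L": L, "M": M, "S": S}
    else:
        raise ValueError(f"unknown family {family!r}")

    result = FitResult(family=family, parameters=params)
    result.discrepancy = fit_discrepancy(empirical_cdf(dist), result)
    return result


def fit_lms_fixed_power(dist: AgeGroupDistribution, L: float) -> FitResult:
    """LMS fit with the Box-Cox power held fixed (L=1 recovers an affine normal)."""
    occupied = dist.pmf > 0
    support = VALUE_BINS[occupied].astype(float)
    w = dist.pmf[occupied]
    M, S, _ = _lms_profile(w, support, L)
    result = FitResult(family="lms", parameters={"L": float(L), "M": M, "S": S})
    result.discrepancy = fit_discrepancy(empirical_cdf(dist), result)
    return result


def fit_discrepancy(cdf: EmpiricalCDF, fit: FitResult) -> float:
    """Sup-norm distance between the empirical and fitted CDFs.

    Evaluated at the integer support values themselves (no half-bin
    continuity correction), so a fitted distribution concentrated at a
    single empirical atom shows its full mismatch there.
    """
    fitted = fit.cdf(cdf.support)
    return float(np.max(np.abs(fitted - cdf.cumulative)))


# ---------------------------------------------------------------------------
# Quantile regression
# ---------------------------------------------------------------------------


@dataclass
class QuantileCurve:
    """Fitted conditional-quantile model at one level p."""

    level: float
    covariate: str  # "linear" (intercept + age) or "per_group" (group constants)
    coefficients: np.ndarray
    ages: np.ndarray  # distinct ages (days) at which fitted values are reported
    fitted: np.ndarray

    def predict(self, age_days: np.ndarray) -> np.ndarray:
        age_days = np.asarray(age_days, dtype=float)
        if self.covariate == "linear":
            return self.coefficients[0] + self.coefficients[1] * age_days
        # per_group: nearest reported age (group constants)
        idx = np.abs(age_days[:, None] - self.ages[None, :]).argmin(axis=1)
        return self.fitted[idx]


def pinball_loss(residuals: np.ndarray, level: float) -> float:
    """Check loss sum: rho_p(u) = u * (p - 1{u < 0})."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (level - (u < 0))))


def _solve_quantile_lp(X: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """Exact quantile regression as a linear program (HiGHS).

    minimize  p * 1'u + (1-p) * 1'v
    s.t.      X b - X c + u - v = y,   u, v, b, c >= 0  (beta = b - c free)
    """
    n, k = X.shape
    c_obj = np.concatenate([np.zeros(2 * k), np.full(n, level), np.full(n, 1 - level)])
    A = sparse.hstack(
        [sparse.csc_matrix(X), -sparse.csc_matrix(X), sparse.eye(n), -sparse.eye(n)],
        format="csc",
    )
    res = optimize.linprog(c_obj, A_eq=A, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile-regression LP failed: {res.message}")
    beta = res.x[:k] - res.x[k : 2 * k]
    return beta


def quantile_regression_centile(
    age_days: np.ndarray,
    values: np.ndarray,
    level: float,
    covariate: str = "linear",
) -> QuantileCurve:
    """Conditional quantile of value given age by pinball-loss minimization.

    ``covariate="linear"`` fits intercept + slope in age (days);
    ``covariate="per_group"`` fits an independent constant per distinct age.
    The LP solution is exact, so on tiny datasets the attained loss matches
    a brute-force search over interpolating lines.
    """
    age_days = np.asarray(age_days, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (0.0 < level < 1.0):
        raise ValueError(f"quantile level must lie in (0, 1), got {level}")
    if age_days.shape != values.shape or age_days.ndim != 1:
        raise ValueError("ages and values must be equal-length 1-D arrays")
    distinct = np.unique(age_days)
    if covariate == "linear":
        if distinct.size < 2:
            raise ValueError("linear quantile regression needs >= 2 distinct ages")
        X = np.column_stack([np.ones_like(age_days), age_days])
        beta = _solve_quantile_lp(X, values, level)
        fitted = beta[0] + beta[1] * distinct
    elif covariate == "per_group":
        # constants per age are just per-age sample quantiles; solve directly
        beta = np.array(
            [np.quantile(values[age_days == a], level) for a in distinct]
        )
        fitted = beta
    else:
        raise ValueError(f"unknown covariate spec {covariate!r}")
    return QuantileCurve(
        level=level, covariate=covariate, coefficients=beta, ages=distinct, fitted=fitted
    )
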