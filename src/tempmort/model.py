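"""Quasi-Poisson DLNM fitting and reduction to cumulative RR curves.

For each city x age group, daily death counts are regressed on the
temperature x lag cross-basis plus confounders (day-of-week indicators,
annual Fourier harmonics, a linear year trend) under a quasi-Poisson model:
Poisson mean structure, variance = dispersion * mean, with the dispersion
estimated from the Pearson chi-square.  The fitted cross-basis coefficients
are then reduced to the cumulative (lag-summed) relative-risk curve on a
0.1 deg C grid, centered at the minimum-mortality temperature (MMT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import splines
from .splines import (
    CrossBasisMatrix,
    SplineSpec,
    build_cross_basis,
    cumulative_exposure_basis,
    default_exposure_spec,
    default_lag_spec,
    percentile,
)

RR_GRID_STEP = 0.1
MMT_WINDOW_PERCENTILES = (1.0, 99.0)
N_HARMONICS = 2
_EPOCH = pd.Timestamp("1970-01-01")


class ConvergenceError(RuntimeError):
    pass


def fit_quasi_poisson(y: np.ndarray, X: np.ndarray, maxiter: int = 100):
    """Quasi-Poisson GLM: Poisson IRLS, Pearson-based dispersion.

    Returns ``(coefficients, covariance, dispersion)`` where
    ``covariance = dispersion * (X' W X)^-1``.  Rank-deficient designs and
    non-convergence are hard errors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be nonnegative integer counts")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in collinearity via tiny QR pivots
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.nonzero(diag < diag.max() * 1e-10)[0].tolist()
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns (0-based): {bad}"
        )

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=1e-10)
    mu = res.mu
    score = X.T @ (y - mu)
    # relative score norm: invariant to column and count scaling
    rel_score = np.linalg.norm(score) / (1.0 + np.linalg.norm(X.T @ y))
    if not np.isfinite(res.deviance) or rel_score > 1e-8:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations; "
            f"last deviance {res.deviance!r}"
        )
    df_resid = len(y) - X.shape[1]
    pearson = float(((y - mu) ** 2 / mu).sum())
    # a saturated design leaves no residual df to estimate overdispersion
    dispersion = pearson / df_resid if df_resid > 0 else 1.0
    cov = dispersion * np.asarray(res.cov_params())  # (X' W X)^-1 at scale 1
    beta = np.asarray(res.params)
    return beta, cov, dispersion


def build_confounders(dates: pd.DatetimeIndex, n_harmonics: int = N_HARMONICS) -> pd.DataFrame:
    """Confounder design: weekly cycle, annual cycle, long-term trend.

    Columns: 6 day-of-week indicators (reference Sunday), ``n_harmonics``
    sine/cosine pairs with a 365.25-day period on days-since-epoch (so the
    phase is identical for dates one full 4-year cycle apart), and a linear
    year trend.  No intercept; the regression adds its own.
    """
    dates = pd.DatetimeIndex(dates)
    if dates.has_duplicates:
        dups = dates[dates.duplicated()].unique()[:5]
        raise ValueError(f"duplicated dates: {list(dups)}")
    cols = {}
    dow = dates.dayofweek  # Monday=0 .. Sunday=6
    for d, name in enumerate(["mon", "tue", "wed", "thu", "fri", "sat"]):
        cols[f"dow_{name}"] = (dow == d).astype(float)
    t = (dates - _EPOCH).days.to_numpy(dtype=float)
    for k in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * k * t / 365.25
        cols[f"harm_sin{k}"] = np.sin(ang)
        cols[f"harm_cos{k}"] = np.cos(ang)
    yr = t / 365.25
    cols["year_trend"] = yr - yr.mean()
    return pd.DataFrame(cols, index=dates)


@dataclass
class FittedTMModel:
    """Fitted quasi-Poisson DLNM for one city x age group."""

    city_id: str
    age_group: str
    coefficients: np.ndarray  # full vector: [intercept, cross-basis, confounders]
    covariance: np.ndarray
    dispersion: float
    cross_basis_slice: slice  # location of cross-basis coefficients
    exposure_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int
    temp_min: float
    temp_max: float
    mmt_window: tuple[float, float]  # 1st-99th percentile of fitting temps

    @property
    def cb_coefficients(self) -> np.ndarray:
        return self.coefficients[self.cross_basis_slice]


@dataclass
class RRCurve:
    """Cumulative relative-risk curve centered at its MMT.

    ``temp_grid`` spans the city's observed temperature range at 0.1 deg C
    steps; ``rr[mmt_index] == 1`` exactly.  Consumers interpolate linearly
    between grid points.
    """

    temp_grid: np.ndarray
    rr: np.ndarray
    mmt: float
    city_id: str = ""
    age_group: str = ""

    def __post_init__(self) -> None:
        if np.any(self.rr <= 0):
            raise ValueError("rr must be positive everywhere")
        if not np.any(np.isclose(self.temp_grid, self.mmt)):
            raise ValueError("mmt must lie on temp_grid")

    def log_rr(self) -> np.ndarray:
        return np.log(self.rr)


def find_mmt(log_rr: np.ndarray, temp_grid: np.ndarray,
             window: tuple[float, float]) -> float:
    """Locate the MMT: argmin of the (un)centered log-RR curve restricted to
    the percentile window; exact ties break toward the warmer temperature.

    An all-equal curve has no information about a minimum; the window midpoint
    is returned with a warning.
    """
    temp_grid = np.asarray(temp_grid, dtype=float)
    log_rr = np.asarray(log_rr, dtype=float)
    lo, hi = window
    mask = (temp_grid >= lo) & (temp_grid <= hi)
    if not mask.any():
        raise ValueError("MMT search window contains no grid points")
    sub_t = temp_grid[mask]
    sub_v = log_rr[mask]
    if np.all(sub_v == sub_v[0]):
        warnings.warn("flat RR curve: MMT set to window midpoint", stacklevel=2)
        mid = 0.5 * (sub_t[0] + sub_t[-1])
        return float(sub_t[np.argmin(np.abs(sub_t - mid))])
    ties = np.nonzero(sub_v == sub_v.min())[0]
    return float(sub_t[ties[-1]])  # grid ascending -> last tie is warmest


def make_temp_grid(tmin: float, tmax: float, step: float = RR_GRID_STEP) -> np.ndarray:
    n = int(np.floor((tmax - tmin) / step + 1e-9)) + 1
    return tmin + step * np.arange(n)


def fit_city_model(
    deaths: pd.Series,
    temps: pd.Series,
    city_id: str = "",
    age_group: str = "",
    exposure_spec: SplineSpec | None = None,
    lag_spec: SplineSpec | None = None,
    max_lag: int = splines.MAX_LAG_DEFAULT,
    n_harmonics: int = N_HARMONICS,
) -> FittedTMModel:
    """Fit the quasi-Poisson DLNM for one city x age group.

    ``deaths`` and ``temps`` must be aligned contiguous daily series covering
    at least two years.  The first ``max_lag`` days are excluded from the
    likelihood (no partial lag history).
    """
    if not deaths.index.equals(temps.index):
        raise ValueError("deaths and temps must share an identical daily index")
    if len(deaths) < 2 * 365:
        raise ValueError("need at least 2 years of aligned daily data")

    tvals = temps.to_numpy(dtype=float)
    if exposure_spec is None:
        exposure_spec = default_exposure_spec(tvals)
    if lag_spec is None:
        lag_spec = default_lag_spec(max_lag)

    cb = build_cross_basis(temps, exposure_spec, lag_spec, max_lag)
    conf = build_confounders(temps.index, n_harmonics=n_harmonics)

    X = np.column_stack([
        np.ones(len(temps)),
        cb.matrix,
        conf.to_numpy(),
    ])
    valid = slice(cb.valid_from, None)
    beta, cov, disp = fit_quasi_poisson(deaths.to_numpy()[valid], X[valid])

    p1, p99 = percentile(tvals, list(MMT_WINDOW_PERCENTILES))
    return FittedTMModel(
        city_id=city_id,
        age_group=age_group,
        coefficients=beta,
        covariance=cov,
        dispersion=disp,
        cross_basis_slice=slice(1, 1 + cb.n_columns),
        exposure_spec=exposure_spec,
        lag_spec=lag_spec,
        max_lag=max_lag,
        temp_min=float(tvals.min()),
        temp_max=float(tvals.max()),
        mmt_window=(float(p1), float(p99)),
    )


def cumulative_rr(model: FittedTMModel, temp_grid: np.ndarray | None = None) -> RRCurve:
    """Reduce a fitted model to its cumulative RR curve.

    The uncentered log-RR at temperature t is the lag-summed cross-basis
    contribution ``sum_l sum_jk B_exp_j(t) B_lag_k(l) beta_jk``; the curve is
    centered at the MMT located on the uncentered curve, so rr(MMT) = 1
    exactly.
    """
    if temp_grid is None:
        temp_grid = make_temp_grid(model.temp_min, model.temp_max)
    temp_grid = np.asarray(temp_grid, dtype=float)
    if temp_grid.min() < model.temp_min - 2.0 or temp_grid.max() > model.temp_max + 2.0:
        raise ValueError("temp_grid must stay within 2 deg C of the observed range")

    basis = cumulative_exposure_basis(
        temp_grid, model.exposure_spec, model.lag_spec, model.max_lag
    )
    log_rr_raw = basis @ model.cb_coefficients
    mmt = find_mmt(log_rr_raw, temp_grid, model.mmt_window)
    mmt_idx = int(np.argmin(np.abs(temp_grid - mmt)))
    centered = log_rr_raw - log_rr_raw[mmt_idx]
    return RRCurve(
        temp_grid=temp_grid,
        rr=np.exp(centered),
        mmt=mmt,
        city_id=model.city_id,
        age_group=model.age_group,
    )
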