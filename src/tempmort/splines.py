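"""Natural cubic spline bases and the exposure x lag cross-basis.

The distributed-lag non-linear model (DLNM) represents the temperature-mortality
surface as a tensor product of two one-dimensional spline bases: one over the
exposure (daily mean temperature) and one over the lag (days since exposure,
0..21).  A natural cubic spline is cubic and twice continuously differentiable
between its boundary knots and constrained to be *linear* beyond them, which
keeps extrapolated relative risks from exploding at the hottest and coldest
observed temperatures.

The basis here uses the truncated-power construction: with knots
``xi_1 < ... < xi_K`` (boundary knots included), define

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)

and take ``{1, x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}}``.  Each difference
``d_k - d_{K-1}`` has its quadratic and cubic terms cancel beyond the last
knot and vanishes below the first, so the span is exactly the natural cubic
splines on those knots, with linear extrapolation built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_LAG_DEFAULT = 21


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for one spline dimension.

    Parameters
    ----------
    internal_knots : tuple of float
        Knots strictly inside the boundary interval (deg C for the exposure
        dimension, days for the lag dimension).
    boundary_knots : (float, float)
        Interval beyond which the basis is linear.
    with_intercept : bool
        Include the constant column.  Used for the lag basis only; the
        exposure basis omits it because the regression has its own intercept.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    with_intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        knots = (lo, *self.internal_knots, hi)
        arr = np.asarray(knots, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("spline knots must be finite")
        if not np.all(np.diff(arr) > 0):
            raise ValueError(
                f"knots must be strictly increasing and internal knots strictly "
                f"inside boundary knots; got internal={self.internal_knots}, "
                f"boundary={self.boundary_knots}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray(
            (self.boundary_knots[0], *self.internal_knots, self.boundary_knots[1]),
            dtype=float,
        )

    @property
    def dim(self) -> int:
        """Number of basis columns."""
        k = len(self.all_knots)
        return k if self.with_intercept else k - 1


def natural_spline_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(n, spec.dim)`` matrix.  Evaluation is defined for any finite
    ``x``; outside the boundary knots each column continues linearly.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    knots = spec.all_knots
    k = len(knots)

    # scaling by the squared boundary span keeps columns O(range) and the
    # design matrix well-conditioned; it changes nothing about the span
    scale = (knots[-1] - knots[0]) ** 2

    def d(i: int) -> np.ndarray:
        num = np.maximum(x - knots[i], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / ((knots[-1] - knots[i]) * scale)

    cols = [np.ones_like(x), x.copy()]
    if k > 2:
        last = d(k - 2)
        for i in range(k - 2):
            cols.append(d(i) - last)
    basis = np.column_stack(cols)
    if not spec.with_intercept:
        basis = basis[:, 1:]
    return basis[0] if scalar else basis


def percentile(values: np.ndarray, q) -> np.ndarray:
    """Project-wide percentile convention: linear interpolation between order
    statistics on the (n-1)-based scale.  Used for knot placement, the MMT
    search window, and extreme-temperature thresholds alike."""
    return np.percentile(np.asarray(values, dtype=float), q, method="linear")


def default_exposure_spec(temps: np.ndarray) -> SplineSpec:
    """Exposure spline for one city: internal knots at the 10th/50th/75th/90th
    temperature percentiles, boundary knots at the observed min/max.

    The median knot matters: without it the whole central span of the
    temperature distribution — where the minimum-mortality temperature
    lives — is a single cubic piece, which rounds the V-shaped
    exposure-response so much that the curve's minimum drifts several
    degrees toward the shallow (cold) side.
    """
    t = np.asarray(temps, dtype=float)
    knots = percentile(t, [10, 50, 75, 90])
    return SplineSpec(
        internal_knots=tuple(float(k) for k in knots),
        boundary_knots=(float(t.min()), float(t.max())),
        with_intercept=False,
    )


def default_lag_spec(max_lag: int = MAX_LAG_DEFAULT) -> SplineSpec:
    """Lag spline over 0..max_lag with intercept; 2 internal knots equally
    spaced on the log(lag+1) scale."""
    log_hi = np.log(max_lag + 1)
    internal = np.exp(np.linspace(0.0, log_hi, 4)[1:3]) - 1.0
    return SplineSpec(
        internal_knots=(float(internal[0]), float(internal[1])),
        boundary_knots=(0.0, float(max_lag)),
        with_intercept=True,
    )


@dataclass
class CrossBasisMatrix:
    """Day x (exposure-dim x lag-dim) DLNM design block.

    ``matrix[d, j * lag_dim + k] = sum_l B_exp_j(T[d-l]) * B_lag_k(l)``.
    Rows before ``valid_from`` lack a full lag history and must not enter the
    likelihood.
    """

    matrix: np.ndarray
    valid_from: int
    exposure_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int = MAX_LAG_DEFAULT
    index: pd.DatetimeIndex | None = field(default=None, repr=False)

    @property
    def n_columns(self) -> int:
        return self.exposure_spec.dim * self.lag_spec.dim

    def valid(self) -> np.ndarray:
        return self.matrix[self.valid_from:]


def build_cross_basis(
    temps: pd.Series,
    exposure_spec: SplineSpec,
    lag_spec: SplineSpec,
    max_lag: int = MAX_LAG_DEFAULT,
) -> CrossBasisMatrix:
    """Build the DLNM cross-basis for a daily temperature series.

    ``temps`` is indexed by contiguous daily dates (or a plain range).  Missing
    values are a hard error naming the offending dates.
    """
    values = np.asarray(temps, dtype=float)
    if len(values) <= max_lag:
        raise ValueError(f"series length {len(values)} must exceed max_lag={max_lag}")
    if np.any(~np.isfinite(values)):
        bad = np.nonzero(~np.isfinite(values))[0]
        if isinstance(temps, pd.Series):
            labels = list(temps.index[bad[:10]])
        else:
            labels = bad[:10].tolist()
        raise ValueError(f"missing/non-finite temperatures at: {labels}")

    exp_basis = natural_spline_basis(values, exposure_spec)  # (n, J)
    lag_basis = natural_spline_basis(
        np.arange(max_lag + 1, dtype=float), lag_spec
    )  # (L+1, K)
    n, j_dim = exp_basis.shape
    k_dim = lag_basis.shape[1]

    cb = np.zeros((n, j_dim * k_dim))
    for lag in range(max_lag + 1):
        # exposure basis evaluated at T[d-lag]; rows d < lag have no history
        shifted = np.zeros_like(exp_basis)
        shifted[lag:] = exp_basis[: n - lag]
        cb += np.einsum("dj,k->djk", shifted, lag_basis[lag]).reshape(n, -1)

    index = temps.index if isinstance(temps, pd.Series) else None
    if isinstance(index, pd.DatetimeIndex) is False:
        index = None
    return CrossBasisMatrix(
        matrix=cb,
        valid_from=max_lag,
        exposure_spec=exposure_spec,
        lag_spec=lag_spec,
        max_lag=max_lag,
        index=index,
    )


def cumulative_exposure_basis(
    temp_grid: np.ndarray, exposure_spec: SplineSpec, lag_spec: SplineSpec,
    max_lag: int = MAX_LAG_DEFAULT,
) -> np.ndarray:
    """Basis for the lag-cumulated exposure-response at constant temperature.

    For a day held at temperature t over the whole lag window, the cross-basis
    row factorises as ``B_exp_j(t) * sum_l B_lag_k(l)``; this returns that
    ``(len(grid), J*K)`` matrix, used to reduce fitted coefficients to the
    overall cumulative relative-risk curve.
    """
    exp_b = natural_spline_basis(np.asarray(temp_grid, dtype=float), exposure_spec)
    lag_sum = natural_spline_basis(
        np.arange(max_lag + 1, dtype=float), lag_spec
    ).sum(axis=0)
    return np.einsum("gj,k->gjk", exp_b, lag_sum).reshape(len(np.atleast_1d(temp_grid)), -1)
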