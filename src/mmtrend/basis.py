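"""Spline bases and the DLNM cross-basis.

The distributed lag non-linear model (DLNM) represents a nonlinear,
lag-distributed exposure-response via a bilinear ("cross") basis: one
natural cubic spline over the exposure (daily mean temperature) and one
over the lag dimension.  The cross-basis column for temperature-basis
function f_j and lag-basis function g_k at day t is

    sum_{l=0..L} f_j(x_{t-l}) * g_k(l)

Natural cubic splines are constructed the way R's ``splines::ns`` does it:
a cubic B-spline basis on the augmented knot sequence with the two
non-natural directions (nonzero second derivative at the boundary knots)
projected out via a QR decomposition, and linear extrapolation beyond the
boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class InvalidSpecError(ValueError):
    """Raised when a spline or cross-basis specification is inconsistent."""


class DataError(ValueError):
    """Raised when input data cannot support the requested construction."""


@dataclass(frozen=True)
class SplineSpec:
    """Knots and intercept flag defining one natural cubic spline basis.

    The basis dimension is ``len(internal_knots) + 1 + with_intercept``.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    with_intercept: bool = False

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        bk = (float(self.boundary_knots[0]), float(self.boundary_knots[1]))
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", bk)
        if bk[0] >= bk[1]:
            raise InvalidSpecError(f"boundary knots not increasing: {bk}")
        if any(not np.isfinite(k) for k in ik + bk):
            raise InvalidSpecError("knots must be finite")
        if any(b - a <= 0 for a, b in zip(ik, ik[1:])):
            raise InvalidSpecError(f"internal knots not strictly increasing: {ik}")
        if ik and (ik[0] <= bk[0] or ik[-1] >= bk[1]):
            raise InvalidSpecError(
                f"internal knots {ik} not strictly inside boundary {bk}"
            )

    @property
    def dim(self) -> int:
        return len(self.internal_knots) + 1 + (1 if self.with_intercept else 0)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Temperature spline, lag spline and maximum lag L of a cross-basis."""

    temp_spline: SplineSpec
    lag_spline: SplineSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.temp_spline.dim < 2:
            raise InvalidSpecError("temperature basis must have dimension >= 2")
        if self.lag_spline.dim < 1:
            raise InvalidSpecError("lag basis must have dimension >= 1")
        if self.max_lag < 0:
            raise InvalidSpecError("max_lag must be >= 0")

    @property
    def vx(self) -> int:
        return self.temp_spline.dim

    @property
    def vl(self) -> int:
        return self.lag_spline.dim


@dataclass
class CrossBasis:
    """The N x (vx*vl) DLNM design block.

    ``matrix`` holds zeros on rows flagged invalid (series edge or missing
    lagged exposure); ``lag_basis_matrix`` is the (L+1) x vl matrix C whose
    row r is the lag basis evaluated at lag r.
    """

    matrix: np.ndarray
    lag_basis_matrix: np.ndarray
    spec: CrossBasisSpec
    valid_rows: np.ndarray = field(repr=False)


def _ns_transform(spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Augmented knot vector and the B-spline -> natural-spline map Z.

    The first B-spline column is dropped (the model intercept takes its
    place) and the two boundary second-derivative constraints are projected
    out via the QR complement, mirroring R's ``ns`` construction.
    """
    lo, hi = spec.boundary_knots
    ik = np.asarray(spec.internal_knots, dtype=float)
    t = np.r_[[lo] * 4, ik, [hi] * 4]
    nb = len(ik) + 4
    # second derivative of every B-spline at the two boundary knots
    eye = np.eye(nb)
    d2 = BSpline(t, eye, 3, extrapolate=True).derivative(2)(np.array([lo, hi]))
    const = d2[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    z = q[:, 2:]
    return t, z


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Rows where ``x`` is NaN are NaN.  Outside the boundary knots the basis
    is extrapolated linearly (value and first derivative at the boundary),
    which is the defining "natural" constraint.  With ``with_intercept``
    the first column is a literal intercept (all ones); the remaining
    columns are the intercept-free basis, so the spanned space is the full
    natural cubic spline space including constants.
    """
    x = np.asarray(x, dtype=float)
    flat = x.ravel()
    t, z = _ns_transform(spec)
    nb = z.shape[0] + 1
    lo, hi = spec.boundary_knots

    out = np.full((flat.size, z.shape[1]), np.nan)
    ok = np.isfinite(flat)
    xi = flat[ok]
    inner = np.clip(xi, lo, hi)
    eye = np.eye(nb)
    spl = BSpline(t, eye, 3, extrapolate=False)
    vals = spl(inner)[:, 1:] @ z
    # linear extrapolation beyond the boundary knots
    outside = (xi < lo) | (xi > hi)
    if outside.any():
        d1 = spl.derivative(1)
        for bnd, mask in ((lo, xi < lo), (hi, xi > hi)):
            if mask.any():
                v0 = (spl(np.array([bnd]))[:, 1:] @ z)[0]
                s0 = (d1(np.array([bnd]))[:, 1:] @ z)[0]
                vals[mask] = v0 + (xi[mask] - bnd)[:, None] * s0
    out[ok] = vals
    if spec.with_intercept:
        ones = np.where(np.isfinite(flat), 1.0, np.nan)[:, None]
        out = np.hstack([ones, out])
    if x.ndim > 1:
        return out.reshape(x.shape + (out.shape[1],))
    return out


def percentile_knots(temps: np.ndarray, percentiles) -> np.ndarray:
    """Empirical quantiles of the non-missing temperatures.

    Linear interpolation between order statistics; the convention matters
    slightly for downstream MMT values so it is fixed here.
    """
    temps = np.asarray(temps, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size < 2:
        raise DataError("need at least 2 non-missing temperatures for knots")
    return np.percentile(temps, np.asarray(percentiles, dtype=float))


def log_spaced_lag_knots(max_lag: int, n_knots: int) -> np.ndarray:
    """Lag knots equally spaced on the log scale over (0, max_lag].

    knot_i = exp(i * log(max_lag) / (n_knots + 1)), i = 1..n_knots.
    """
    if max_lag < 1:
        raise InvalidSpecError("max_lag must be >= 1")
    if n_knots < 1:
        raise InvalidSpecError("n_knots must be >= 1")
    if n_knots >= max_lag:
        raise InvalidSpecError("n_knots must be < max_lag")
    i = np.arange(1, n_knots + 1)
    return np.exp(i * np.log(max_lag) / (n_knots + 1))


def temperature_spline_spec(
    temps: np.ndarray,
    knot_percentiles=(10.0, 75.0, 90.0),
) -> SplineSpec:
    """Temperature basis spec: percentile internal knots, min/max boundary."""
    temps = np.asarray(temps, dtype=float)
    finite = temps[np.isfinite(temps)]
    if finite.size < 2:
        raise DataError("need at least 2 non-missing temperatures")
    knots = percentile_knots(finite, knot_percentiles)
    lo, hi = float(finite.min()), float(finite.max())
    if np.unique(knots).size != knots.size or knots[0] <= lo or knots[-1] >= hi:
        raise InvalidSpecError(
            "degenerate temperature knots (ties or knots at the range edge)"
        )
    return SplineSpec(tuple(knots), (lo, hi), with_intercept=False)


def lag_spline_spec(max_lag: int, n_knots: int = 3) -> SplineSpec:
    """Lag basis spec: intercept, log-spaced internal knots, boundary [0, L]."""
    knots = log_spaced_lag_knots(max_lag, n_knots)
    return SplineSpec(tuple(knots), (0.0, float(max_lag)), with_intercept=True)


def build_cross_basis(x: np.ndarray, spec: CrossBasisSpec) -> CrossBasis:
    """Assemble the cross-basis matrix for a daily temperature series.

    Row t, column (j, k) is sum_l f_j(x_{t-l}) g_k(l).  Rows t <= L-1
    (0-based: the first L rows) or with any missing lagged temperature are
    flagged invalid and zeroed.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    L = spec.max_lag
    if n <= L:
        raise DataError(f"series length {n} must exceed max_lag {L}")

    f = natural_cubic_basis(x, spec.temp_spline)  # N x vx, NaN where missing
    c = natural_cubic_basis(np.arange(L + 1, dtype=float), spec.lag_spline)
    vx, vl = spec.vx, spec.vl

    m = np.zeros((n, vx, vl))
    valid = np.ones(n, dtype=bool)
    valid[:L] = False
    for lag in range(L + 1):
        fl = np.empty_like(f)
        fl[:lag] = np.nan
        fl[lag:] = f[: n - lag]
        bad = ~np.isfinite(fl[:, 0])
        valid &= ~bad | (np.arange(n) < L)
        fl = np.where(np.isfinite(fl), fl, 0.0)
        m += fl[:, :, None] * c[lag][None, None, :]
    valid[:L] = False
    m[~valid] = 0.0
    return CrossBasis(
        matrix=m.reshape(n, vx * vl),
        lag_basis_matrix=c,
        spec=spec,
        valid_rows=valid,
    )
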