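"""Clipping-error estimation from scan stacks via censored moment fitting.

Over-saturation: a pixel whose raw signal X ~ N(mu, sigma^2) exceeds the
grayscale ceiling ``c_a`` is recorded as ``c_a`` in single scans, so the
averaged value is reduced by the partial expectation

    U = E[(X - c_a)^+] = (mu - c_a) * Phi((mu - c_a)/sigma)
                         + sigma * phi((mu - c_a)/sigma).

(mu, sigma) are recovered per pixel by the method of moments applied to
the right-censored sample of scan values: the mean and variance of the
boundary-concentrated (clipped) Normal are matched to the sample moments.

Under-saturation: offset subtraction removes ``c_b`` intensity units and
zeroes what falls below, inflating the averaged value by

    L = E[(c_b - X)^+] = integral_0^{c_b} (c_b - x) w(x) dx,

where the raw low-intensity signal X is modelled by a two-parameter
Weibull density w, fitted by moments to the left-censored sample (values
recorded as 0 stand for X <= c_b).

Per-pixel fits on 8-frame samples are necessarily noisy; reliable error
estimates come from averaging U and L over all pixels sharing the same
rounded averaged intensity k, which is what :func:`error_profile` does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import erfcx, gamma as gamma_fn, gammainc, gammaincc, ndtr

from .exceptions import (
    EstimationError,
    InfeasibleError,
    InsufficientDataError,
    StructuralError,
)
from .simulate import ScanStack

__all__ = [
    "CensoredGaussian",
    "CensoredWeibull",
    "PixelErrorProfile",
    "ObjectError",
    "fit_censored_gaussian_moments",
    "upper_pixel_error",
    "fit_censored_weibull_moments",
    "lower_pixel_error",
    "error_profile",
    "object_error",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)
_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)

# bracket for the standardized censoring margin alpha = (mu - c_a)/sigma
_ALPHA_LO, _ALPHA_HI = -12.0, 12.0
# bracket for the Weibull shape
_SHAPE_LO, _SHAPE_HI = 0.08, 80.0


@dataclass(frozen=True)
class CensoredGaussian:
    """Normal location/scale recovered from a right-censored sample."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.isfinite(self.sigma)) or self.sigma < 0:
            raise EstimationError("invalid Gaussian parameters")


@dataclass(frozen=True)
class CensoredWeibull:
    """Two-parameter Weibull (shape, scale) from a left-censored sample."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        ok = (
            np.isfinite(self.shape)
            and np.isfinite(self.scale)
            and self.shape > 0
            and self.scale > 0
        )
        if not ok:
            raise EstimationError("invalid Weibull parameters")


@dataclass
class PixelErrorProfile:
    """Averaged clipping errors per intensity level k in [0..c_a].

    ``U[k]``/``L[k]`` are the mean upper/lower pixel errors over pixels
    whose rounded averaged intensity is k (zero contribution from pixels
    with no clipped frame), ``E = U + L``, ``n[k]`` counts included pixels
    and ``n_excluded[k]`` pixels dropped because their fit was infeasible
    or failed.  ``reliable[k]`` is False above the estimability ceiling.
    """

    U: np.ndarray
    L: np.ndarray
    E: np.ndarray
    n: np.ndarray
    n_excluded: np.ndarray
    reliable: np.ndarray
    c_a: int
    c_b: float
    upper_map: np.ndarray | None = None
    lower_map: np.ndarray | None = None
    valid_map: np.ndarray | None = None

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.c_a + 1)

    def error_map(self) -> np.ndarray:
        """Per-pixel total error (NaN where estimation failed)."""
        if self.upper_map is None or self.lower_map is None:
            raise StructuralError("profile was computed without per-pixel maps")
        total = self.upper_map + self.lower_map
        return np.where(self.valid_map, total, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.levels,
                "U": self.U,
                "L": self.L,
                "E": self.E,
                "n": self.n,
                "n_excluded": self.n_excluded,
                "reliable": self.reliable.astype(int),
            }
        )


@dataclass(frozen=True)
class ObjectError:
    """Mean pixel error over the N pixels of one mask object."""

    object_id: int
    n_pixels: int
    mean_error: float


# ---------------------------------------------------------------------------
# right-censored Gaussian, method of moments
# ---------------------------------------------------------------------------

def _phi(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


def _mills(a):
    """Phi(-a)/phi(a), stable for large |a| via erfcx."""
    return _SQRT_HALF_PI * erfcx(a / math.sqrt(2.0))


def _pos_part_mean(a):
    """E[(Z + a)^+] for standard normal Z."""
    return a * ndtr(a) + _phi(a)


def _censored_ratio(alpha):
    """Var(W)/E[W]^2 for W = min(Z + alpha, 0), Z standard normal.

    Strictly increasing in alpha: ~1/alpha^2 for alpha -> -inf (no
    censoring) and unbounded for heavy censoring.  Written in terms of the
    Mills ratio so the heavy-censoring tail does not cancel numerically.
    """
    alpha = np.asarray(alpha, dtype=float)
    R = _mills(alpha)
    ew_over_phi = alpha * R - 1.0          # E[W]/phi(alpha)  (negative)
    ew2_over_phi = (1.0 + alpha**2) * R - alpha  # E[W^2]/phi(alpha)
    return ew2_over_phi / (_phi(alpha) * ew_over_phi**2) - 1.0


def _solve_gaussian_censored(m, v, c_a):
    """Vectorized moment inversion for the right-clipped Normal.

    ``m``/``v`` are sample mean and variance (ddof=1) of clipped values
    Y = min(X, c_a).  Returns (mu, sigma, status) with status 0 = solved,
    1 = censoring negligible (plain moments returned), 2 = failed.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    target = v / np.square(c_a - m)
    lo = np.full(m.shape, _ALPHA_LO)
    hi = np.full(m.shape, _ALPHA_HI)
    r_lo = _censored_ratio(_ALPHA_LO)
    r_hi = _censored_ratio(_ALPHA_HI)

    status = np.zeros(m.shape, dtype=np.int8)
    status[target <= r_lo] = 1
    status[target >= r_hi] = 2
    solvable = status == 0

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _censored_ratio(mid) < target
        lo = np.where(solvable & too_low, mid, lo)
        hi = np.where(solvable & ~too_low, mid, hi)
    alpha = 0.5 * (lo + hi)

    # E[(Z - alpha)^+] = phi(alpha) * (1 - alpha * Mills(alpha))
    h_neg = _phi(alpha) * (1.0 - alpha * _mills(alpha))
    sigma = np.where(solvable, (c_a - m) / h_neg, np.sqrt(v))
    mu = np.where(solvable, c_a + sigma * alpha, m)
    return mu, sigma, status


def fit_censored_gaussian_moments(values, c_a: float) -> CensoredGaussian:
    """Method-of-moments Normal fit to a right-censored scan sample.

    Values equal to ``c_a`` are treated as censored (true value at or
    above the ceiling).  With no censored value the moment equations
    reduce to the plain sample mean and standard deviation.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError("need at least 2 scan values")
    n_cens = int(np.sum(x >= c_a))
    if n_cens == x.size:
        raise InfeasibleError(
            "all scan values are clipped at c_a; the true mean cannot be "
            "estimated"
        )
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if n_cens == 0:
        return CensoredGaussian(mu=m, sigma=math.sqrt(v))
    if v == 0.0:  # unreachable with mixed censored/uncensored integers
        return CensoredGaussian(mu=m, sigma=0.0)
    mu, sigma, status = _solve_gaussian_censored(m, v, c_a)
    if status[0] == 2:
        raise EstimationError("censored-moment equations have no root in bounds")
    return CensoredGaussian(mu=float(mu[0]), sigma=float(sigma[0]))


def _upper_error_closed(mu, sigma, c_a):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    safe = np.where(sigma > 0, sigma, 1.0)
    with np.errstate(invalid="ignore"):
        u = np.where(
            sigma > 0,
            safe * _pos_part_mean((mu - c_a) / safe),
            np.maximum(mu - c_a, 0.0),
        )
    return u


def upper_pixel_error(params: CensoredGaussian, c_a: float) -> float:
    """Expected over-saturation loss E[(X - c_a)^+] in closed form."""
    return float(_upper_error_closed(params.mu, params.sigma, c_a))


# ---------------------------------------------------------------------------
# left-censored Weibull, method of moments
# ---------------------------------------------------------------------------

def _weibull_t(shape, scale, c_b):
    """t = (c_b/scale)^shape with overflow-safe exponentiation."""
    if c_b <= 0:
        return np.zeros(np.broadcast(shape, scale).shape)
    with np.errstate(divide="ignore"):
        logt = shape * (np.log(c_b) - np.log(scale))
    return np.exp(np.clip(logt, -745.0, 709.0))


def _weibull_excess_mean(shape, scale, c_b):
    """E[O] for O = (X - c_b)^+, X ~ Weibull(shape, scale).

    E[O] = scale * Gamma(1 + 1/k) * Q(1/k, t) with t = (c_b/scale)^k and
    Q the regularized upper incomplete gamma.
    """
    shape = np.asarray(shape, dtype=float)
    scale = np.asarray(scale, dtype=float)
    t = _weibull_t(shape, scale, c_b)
    inv = 1.0 / shape
    return scale * gamma_fn(1.0 + inv) * gammaincc(inv, t)


def _weibull_excess_moments(shape, scale, c_b):
    """First two moments of O = (X - c_b)^+ for X ~ Weibull(shape, scale).

    Via upper incomplete gamma functions:
        E[O]   = scale * Gamma(1 + 1/k) * Q(1/k, t) ,
        E[O^2] = scale^2 * Gamma(1 + 2/k) * Q(2/k, t) - 2 * c_b * E[O] ,
    with t = (c_b/scale)^k and Q the regularized upper incomplete gamma.
    """
    shape = np.asarray(shape, dtype=float)
    scale = np.asarray(scale, dtype=float)
    t = _weibull_t(shape, scale, c_b)
    inv = 1.0 / shape
    m1 = scale * gamma_fn(1.0 + inv) * gammaincc(inv, t)
    m2 = scale**2 * gamma_fn(1.0 + 2.0 * inv) * gammaincc(2.0 * inv, t) - 2.0 * c_b * m1
    return m1, np.maximum(m2, 1e-300)


def _solve_weibull_scale(shape, M1, c_b, iters: int = 28):
    """Given shape, find scale with E[O](shape, scale) = M1 (bisection).

    E[O] is strictly increasing in scale.  Since O >= X - c_b, the mean is
    bounded below by scale*Gamma(1+1/k) - c_b, which yields a safe upper
    bracket.
    """
    shape = np.asarray(shape, dtype=float)
    inv = 1.0 / shape
    g1 = gamma_fn(1.0 + inv)
    logcb = math.log(c_b) if c_b > 0 else -np.inf
    lo = np.full(np.shape(M1), 1e-8)
    hi = 4.0 * (M1 + c_b + 1.0) / np.minimum(g1, 1.0)
    for _ in range(iters):
        mid = np.sqrt(lo * hi)  # bisection in log space
        if c_b > 0:
            t = np.exp(np.clip(shape * (logcb - np.log(mid)), -745.0, 709.0))
        else:
            t = 0.0
        lower = mid * g1 * gammaincc(inv, t) < M1
        lo = np.where(lower, mid, lo)
        hi = np.where(lower, hi, mid)
    return np.sqrt(lo * hi)


def _solve_weibull_censored(M1, M2, c_b, outer_iters: int = 30):
    """Vectorized moment inversion for the left-censored Weibull.

    ``M1``/``M2`` are the sample mean and raw second moment of the excess
    O = (X - c_b)^+ (censored observations contribute 0).  The normalized
    second moment E[O^2]/E[O]^2 decreases monotonically in the shape at
    fixed mean, enabling a nested bisection: outer over the shape, inner
    over the scale that matches the mean.  Returns (shape, scale, ok).
    """
    M1 = np.atleast_1d(np.asarray(M1, dtype=float))
    M2 = np.atleast_1d(np.asarray(M2, dtype=float))
    target = M2 / np.square(M1)

    def ratio(shape):
        sc = _solve_weibull_scale(shape, M1, c_b)
        m1, m2 = _weibull_excess_moments(shape, sc, c_b)
        return m2 / np.square(m1), sc

    r_lo, _ = ratio(np.full(M1.shape, _SHAPE_LO))
    r_hi, _ = ratio(np.full(M1.shape, _SHAPE_HI))
    ok = (M1 > 0) & np.isfinite(target) & (target < r_lo) & (target > r_hi)

    lo = np.full(M1.shape, _SHAPE_LO)
    hi = np.full(M1.shape, _SHAPE_HI)
    for _ in range(outer_iters):
        mid = np.sqrt(lo * hi)
        r_mid, _ = ratio(mid)
        # ratio decreases with shape: ratio > target means shape too small
        small = r_mid > target
        lo = np.where(ok & small, mid, lo)
        hi = np.where(ok & ~small, mid, hi)
    shape = np.sqrt(lo * hi)
    scale = _solve_weibull_scale(shape, np.where(ok, M1, 1.0), c_b)
    return shape, scale, ok


def _plain_weibull_moments(m, v):
    """Uncensored Weibull method of moments: shape from the CV relation."""
    target = (v + m**2) / m**2  # E[X^2]/E[X]^2 = Gamma(1+2/k)/Gamma(1+1/k)^2

    def ratio(k):
        return gamma_fn(1.0 + 2.0 / k) / gamma_fn(1.0 + 1.0 / k) ** 2

    lo, hi = _SHAPE_LO, _SHAPE_HI
    if not (ratio(hi) < target < ratio(lo)):
        raise EstimationError("sample CV outside the Weibull moment range")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if ratio(mid) > target:
            lo = mid
        else:
            hi = mid
    shape = math.sqrt(lo * hi)
    scale = m / gamma_fn(1.0 + 1.0 / shape)
    return CensoredWeibull(shape=shape, scale=scale)


def fit_censored_weibull_moments(values, c_b: float) -> CensoredWeibull:
    """Method-of-moments Weibull fit to a left-censored scan sample.

    ``values`` are on the raw (pre-offset-subtraction) intensity scale:
    an observed frame value f corresponds to raw value ``f + c_b`` when
    f > 0, and to a censored observation (raw value <= c_b, recorded as
    ``c_b``) when f = 0.  Values <= ``c_b`` are treated as censored.  With
    no censored value the fit reduces to the plain Weibull method of
    moments (shape from the coefficient of variation).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError("need at least 2 scan values")
    cens = x <= c_b
    if np.all(cens):
        raise InfeasibleError(
            "all scan values are clipped at zero; the true mean cannot be "
            "estimated"
        )
    if not np.any(cens):
        return _plain_weibull_moments(float(x.mean()), float(x.var(ddof=1)))
    excess = np.maximum(x - c_b, 0.0)
    M1 = float(excess.mean())
    M2 = M1**2 + float(excess.var(ddof=1))
    shape, scale, ok = _solve_weibull_censored(M1, M2, c_b)
    if not ok[0]:
        raise EstimationError("censored Weibull moments have no root in bounds")
    return CensoredWeibull(shape=float(shape[0]), scale=float(scale[0]))


def _lower_error_closed(shape, scale, c_b):
    """E[(c_b - X)^+] = c_b - scale * Gamma(1+1/k) * P(1/k, t)."""
    if c_b <= 0:
        return np.zeros(np.broadcast(np.asarray(shape), np.asarray(scale)).shape)
    shape = np.asarray(shape, dtype=float)
    scale = np.asarray(scale, dtype=float)
    t = _weibull_t(shape, scale, c_b)
    inv = 1.0 / shape
    return c_b - scale * gamma_fn(1.0 + inv) * gammainc(inv, t)


def lower_pixel_error(params: CensoredWeibull, c_b: float) -> float:
    """Expected under-saturation inflation E[(c_b - X)^+].

    Computed by adaptive quadrature of (c_b - x) w(x) over [0, c_b]; the
    incomplete-gamma closed form is used as an internal cross-check in the
    vectorized profile path.
    """
    if c_b < 0:
        raise EstimationError("c_b must be >= 0")
    if c_b == 0:
        return 0.0
    k, lam = params.shape, params.scale

    def integrand(x):
        z = (x / lam) ** k
        return (c_b - x) * (k / lam) * (x / lam) ** (k - 1.0) * np.exp(-z)

    val, _ = integrate.quad(integrand, 0.0, c_b, limit=200)
    return float(max(val, 0.0))


# ---------------------------------------------------------------------------
# per-intensity profile and object aggregation
# ---------------------------------------------------------------------------

def error_profile(
    stack: ScanStack,
    c_b: float | None = None,
    ceiling: int = 250,
    keep_maps: bool = True,
) -> PixelErrorProfile:
    """Estimate U_k, L_k and E_k = U_k + L_k from one scan stack.

    Per pixel the Gaussian/upper model is fitted when any frame sits at
    ``c_a`` and the Weibull/lower model when any frame sits at 0 (a pixel
    is normally corrupted by only one kind of saturation); pixels with no
    clipped frame contribute zero error.  Pixels whose fit is infeasible
    (all frames censored) or fails numerically are excluded from the level
    means and counted in ``n_excluded``.  Levels above ``ceiling`` are
    flagged unreliable: the topmost intensities are so strongly clipped
    that their estimates cannot be trusted.
    """
    frames = stack.float_frames()
    c_a = float(stack.config.c_a)
    if c_b is None:
        c_b = stack.config.offset_units
    n, H, W = frames.shape

    avg = frames.mean(axis=0)
    var = frames.var(axis=0, ddof=1)
    at_top = stack.frames == stack.config.c_a
    at_bottom = stack.frames == 0
    any_top = at_top.any(axis=0)
    all_top = at_top.all(axis=0)
    any_bottom = at_bottom.any(axis=0)
    all_bottom = at_bottom.all(axis=0)

    upper_map = np.zeros((H, W))
    lower_map = np.zeros((H, W))
    valid = np.ones((H, W), dtype=bool)
    valid[all_top] = False
    valid[all_bottom] = False

    # 8-frame integer samples realize few distinct (mean, variance) pairs,
    # so each branch solves its moment system once per unique pair only.
    sel_up = any_top & ~all_top
    if np.any(sel_up):
        pairs = np.column_stack([avg[sel_up], var[sel_up]])
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        mu, sigma, status = _solve_gaussian_censored(uniq[:, 0], uniq[:, 1], c_a)
        u = _upper_error_closed(mu, sigma, c_a)
        tmp = np.zeros((H, W))
        tmp[sel_up] = np.where(status == 2, 0.0, u)[inverse]
        failed = np.zeros((H, W), dtype=bool)
        failed[sel_up] = (status == 2)[inverse]
        valid &= ~failed
        upper_map = tmp

    sel_lo = any_bottom & ~all_bottom & (c_b > 0)
    if np.any(sel_lo):
        pairs = np.column_stack([avg[sel_lo], var[sel_lo]])
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        M1u = uniq[:, 0]
        M2u = M1u**2 + uniq[:, 1]
        shape, scale, ok = _solve_weibull_censored(M1u, M2u, c_b)
        low = _lower_error_closed(shape, scale, c_b)
        tmp = np.zeros((H, W))
        tmp[sel_lo] = np.where(ok, low, 0.0)[inverse]
        failed = np.zeros((H, W), dtype=bool)
        failed[sel_lo] = (~ok)[inverse]
        valid &= ~failed
        lower_map = tmp

    k_map = np.rint(avg).astype(np.int64).ravel()
    v = valid.ravel()
    n_levels = stack.config.c_a + 1
    counts = np.bincount(k_map[v], minlength=n_levels)
    excl = np.bincount(k_map[~v], minlength=n_levels)
    u_sum = np.bincount(k_map[v], weights=upper_map.ravel()[v], minlength=n_levels)
    l_sum = np.bincount(k_map[v], weights=lower_map.ravel()[v], minlength=n_levels)
    with np.errstate(invalid="ignore"):
        U = np.where(counts > 0, u_sum / np.maximum(counts, 1), np.nan)
        L = np.where(counts > 0, l_sum / np.maximum(counts, 1), np.nan)
    reliable = np.arange(n_levels) <= ceiling
    return PixelErrorProfile(
        U=U,
        L=L,
        E=U + L,
        n=counts,
        n_excluded=excl,
        reliable=reliable,
        c_a=stack.config.c_a,
        c_b=float(c_b),
        upper_map=upper_map if keep_maps else None,
        lower_map=lower_map if keep_maps else None,
        valid_map=valid if keep_maps else None,
    )


def object_error(pixel_errors: np.ndarray, mask: np.ndarray) -> list[ObjectError]:
    """Mean pixel error per connected mask component (8-connectivity).

    ``pixel_errors`` may contain NaN for pixels whose estimate failed;
    those are skipped in the mean but still counted in N.
    """
    from skimage.measure import label

    pixel_errors = np.asarray(pixel_errors, dtype=float)
    mask = np.asarray(mask)
    if pixel_errors.shape != mask.shape:
        raise StructuralError("mask shape does not match the error map")
    labels = label(mask > 0, connectivity=2)
    n_obj = labels.max()
    out: list[ObjectError] = []
    if n_obj == 0:
        return out
    flat_lab = labels.ravel()
    flat_err = pixel_errors.ravel()
    good = np.isfinite(flat_err)
    n_pix = np.bincount(flat_lab, minlength=n_obj + 1)
    n_good = np.bincount(flat_lab[good], minlength=n_obj + 1)
    sums = np.bincount(flat_lab[good], weights=flat_err[good], minlength=n_obj + 1)
    for obj in range(1, n_obj + 1):
        mean = sums[obj] / n_good[obj] if n_good[obj] > 0 else float("nan")
        out.append(ObjectError(object_id=obj, n_pixels=int(n_pix[obj]), mean_error=float(mean)))
    return out
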