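"""Harmonic regression of a single pixel's intensity series.

The model for the green-channel intensity y(t), with t in cardiac-cycle
fractions, is

    y(t) = f_p(t) + f_np(t) + eps_t

where the periodic trend f_p is a truncated Fourier series of the cardiac
fundamental (first K harmonics; K = 2 by default),

    f_p(t) = a0 + sum_n a_n cos(w n t) + b_n sin(w n t),

the non-periodic trend f_np is a linear spline with knots at whole cycles
(t = 1, 2 for a three-cycle segment) absorbing slow movement artifact,

    f_np(t) = b0 + b1 t + b2 (t-1)_+ + b3 (t-2)_+,

and the error eps_t is a stationary first-order autoregression,
eps_t = rho * eps_{t-1} + u_t with white-noise innovations u_t. The
autoregressive parameter rho is estimated by restricted maximum likelihood
(REML); the regression coefficients are the generalized-least-squares
solution under the AR(1) covariance at the REML optimum.

From the fitted periodic component two scalar summaries are derived per
pixel: the harmonic regression wave amplitude (HRWa, peak-to-trough range
over one cycle) and the time to trough (location of the wave minimum in
cycle fractions, the "foot" of the pulse wave).

The fundamental angular frequency w defaults to 2*pi per cycle so that the
first harmonic has period one cardiac cycle (``basis="2pi"``); the
alternative ``basis="pi"`` (period-two fundamental) is kept as a switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PixelSeries",
    "HarmonicFit",
    "DesignMatrix",
    "build_design_matrix",
    "fit_harmonic_regression",
    "reml_profile",
    "select_order_aic",
    "periodic_component",
    "hrw_amplitude",
    "time_to_trough",
]

_TROUGH_GRID = 4096  # grid density for peak/trough location on [0, 1)
RHO_BOUND = 0.99     # search interval for the AR(1) parameter


class FitError(RuntimeError):
    """Harmonic regression could not be fitted at all."""


@dataclass(frozen=True)
class PixelSeries:
    """One pixel's intensity series on the cycle-fraction time grid."""

    y: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)
        if y.shape != t.shape or y.ndim != 1:
            raise ValueError("y and t must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class HarmonicFit:
    """All estimated parameters of one pixel's harmonic regression."""

    a0: float
    harmonics: tuple[tuple[float, float], ...]  # (a_n, b_n), n = 1..K
    spline: tuple[float, float, float, float]   # (b0, b1, b2, b3); b0 == 0
    rho: float
    sigma_u: float
    loglik_reml: float
    loglik_ml: float
    aic: float
    hrw_amplitude: float
    time_to_trough: float                       # NaN when amplitude is 0
    basis: str = "2pi"
    converged: bool = True
    flags: tuple[str, ...] = ()

    @property
    def order(self) -> int:
        return len(self.harmonics)

    @property
    def omega(self) -> float:
        return 2.0 * math.pi if self.basis == "2pi" else math.pi

    def to_dict(self) -> dict:
        d = {"a0": self.a0}
        for n, (a, b) in enumerate(self.harmonics, start=1):
            d[f"a{n}"] = a
            d[f"b{n}_sin"] = b
        d.update(
            spline_b0=self.spline[0], spline_b1=self.spline[1],
            spline_b2=self.spline[2], spline_b3=self.spline[3],
            rho=self.rho, sigma_u=self.sigma_u,
            loglik_reml=self.loglik_reml, loglik_ml=self.loglik_ml, aic=self.aic,
            hrw_amplitude=self.hrw_amplitude, time_to_trough=self.time_to_trough,
            basis=self.basis, converged=self.converged, flags=";".join(self.flags),
        )
        return d


@dataclass(frozen=True)
class DesignMatrix:
    """Regression design with column bookkeeping.

    Columns: intercept, t, truncated-linear spline terms (z)_+ per retained
    knot, then cos/sin pairs for harmonics 1..K. Knots whose truncated term
    is identically zero over the data span are dropped (rank deficiency).
    """

    X: np.ndarray
    order: int
    knots: tuple[float, ...]          # knots requested
    retained_knots: tuple[float, ...]  # knots whose column survived
    basis: str

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def _omega(basis: str) -> float:
    if basis == "2pi":
        return 2.0 * math.pi
    if basis == "pi":
        return math.pi
    raise ValueError(f"basis must be 'pi' or '2pi', got {basis!r}")


def build_design_matrix(
    t: np.ndarray,
    order: int = 2,
    knots: tuple[float, ...] = (1.0, 2.0),
    basis: str = "2pi",
) -> DesignMatrix:
    """Build the harmonic + spline design for time grid ``t``.

    Truncated-linear terms ``(t - k)_+`` with ``(z)_+ = max(z, 0)`` model the
    drift; harmonics of the cardiac fundamental model the pulse. A knot at or
    beyond the last time point yields an all-zero column and is dropped with
    a warning.
    """
    t = np.asarray(t, dtype=float)
    if order < 1:
        raise ValueError(f"harmonic order must be >= 1, got {order}")
    w = _omega(basis)
    cols = [np.ones_like(t), t]
    retained = []
    for k in knots:
        term = np.maximum(t - k, 0.0)
        if np.any(term > 0):
            cols.append(term)
            retained.append(float(k))
        else:
            warnings.warn(
                f"spline knot t={k} lies outside the data span; column dropped",
                RuntimeWarning, stacklevel=2,
            )
    for n in range(1, order + 1):
        cols.append(np.cos(w * n * t))
        cols.append(np.sin(w * n * t))
    X = np.column_stack(cols)
    return DesignMatrix(X=X, order=order, knots=tuple(float(k) for k in knots),
                        retained_knots=tuple(retained), basis=basis)


def _ar1_whiten(v: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening transform along axis 0.

    First observation scaled by sqrt(1 - rho^2); subsequent rows become
    v_t - rho * v_{t-1}. The transformed noise has the innovation variance.
    """
    out = np.empty_like(v, dtype=float)
    out[0] = math.sqrt(1.0 - rho * rho) * v[0]
    out[1:] = v[1:] - rho * v[:-1]
    return out


def _gls_at_rho(y: np.ndarray, X: np.ndarray, rho: float):
    """GLS solution and residual sum of squares under AR(1) with given rho."""
    ys = _ar1_whiten(y, rho)
    Xs = _ar1_whiten(X, rho)
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    return beta, rss, rank, Xs


def _loglik_parts(y: np.ndarray, X: np.ndarray, rho: float):
    """(beta, rss, log|C|, log|X' C^-1 X|) at the GLS solution for rho.

    C is the AR(1) covariance shape whose whitened innovations have unit
    variance, so log|C| = -log(1 - rho^2).
    """
    beta, rss, rank, Xs = _gls_at_rho(y, X, rho)
    logdet_c = -math.log1p(-rho * rho)
    sign, logdet_xtx = np.linalg.slogdet(Xs.T @ Xs)
    if sign <= 0:
        logdet_xtx = -np.inf
    return beta, rss, logdet_c, logdet_xtx


def reml_profile(y: np.ndarray, X: np.ndarray, rho: float) -> float:
    """Restricted log-likelihood of the AR(1) model, profiled over beta, sigma.

    At ``rho = 0`` the whitening is the identity and this reduces to the
    ordinary-least-squares restricted likelihood.
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    n, p = X.shape
    beta, rss, logdet_c, logdet_xtx = _loglik_parts(y, X, rho)
    df = n - p
    if df <= 0:
        raise FitError(f"series too short: n={n} <= p={p}")
    if rss <= 0:
        return np.inf  # degenerate (perfect fit); handled by the caller
    sigma2 = rss / df
    return -0.5 * (df * (math.log(2 * math.pi * sigma2) + 1.0)
                   + logdet_c + logdet_xtx)


def _ml_loglik(y: np.ndarray, X: np.ndarray, rho: float) -> float:
    """Full (unrestricted) profile log-likelihood, used for AIC."""
    n = len(y)
    _, rss, logdet_c, _ = _loglik_parts(y, X, rho)
    if rss <= 0:
        return np.inf
    sigma2 = rss / n
    return -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet_c)


def _unpack(beta: np.ndarray, design: DesignMatrix):
    """Split a coefficient vector into intercept, spline and harmonic parts."""
    a0 = float(beta[0])
    b1 = float(beta[1])
    spline_terms = {k: 0.0 for k in design.knots}
    pos = 2
    for k in design.retained_knots:
        spline_terms[k] = float(beta[pos])
        pos += 1
    harmonics = []
    for _ in range(design.order):
        harmonics.append((float(beta[pos]), float(beta[pos + 1])))
        pos += 2
    knot_coefs = [spline_terms[k] for k in design.knots]
    knot_coefs += [0.0] * (2 - len(knot_coefs))
    spline = (0.0, b1, knot_coefs[0], knot_coefs[1])
    return a0, tuple(harmonics), spline


def fit_harmonic_regression(
    series: PixelSeries,
    order: int = 2,
    knots: tuple[float, ...] | None = None,
    basis: str = "2pi",
    rho_tol: float = 1e-6,
) -> HarmonicFit:
    """Fit the harmonic + spline + AR(1) model to one pixel series.

    rho is found by bounded scalar maximization of the restricted likelihood
    over (-0.99, 0.99); the coefficients are the exact GLS solution at that
    rho. Degenerate series (constant intensity, or an exact noiseless model
    realization) yield a flagged fit rather than an exception, so whole-stack
    mapping never aborts.
    """
    y, t = series.y, series.t
    if knots is None:
        # every integer cycle boundary interior to the span
        knots = tuple(float(k) for k in range(1, int(math.ceil(t[-1]))))
        if not knots:
            knots = (1.0,)
    design = build_design_matrix(t, order=order, knots=knots, basis=basis)
    X = design.X
    n, p = X.shape
    if n < p + 2:
        raise FitError(f"series of length {n} too short for {p} parameters")

    flags: list[str] = []
    converged = True

    # OLS first: detects degenerate pixels and exact model realizations,
    # where the REML profile diverges.
    beta0, rss0, rank0, _ = _gls_at_rho(y, X, 0.0)
    scale = float(np.mean(y * y)) + 1e-300
    if rank0 < p:
        flags.append("rank_deficient")
    if rss0 / n <= 1e-18 * scale:
        rho_hat = 0.0
        beta = beta0
        sigma_u = math.sqrt(max(rss0, 0.0) / max(n - p, 1))
        ll_reml = np.inf
        ll_ml = np.inf
        aic = -np.inf
        flags.append("perfect_fit")
        if float(np.var(y)) <= 1e-18 * scale:
            flags.append("degenerate")
    else:
        res = minimize_scalar(
            lambda r: -reml_profile(y, X, r),
            bounds=(-RHO_BOUND, RHO_BOUND),
            method="bounded",
            options={"xatol": rho_tol},
        )
        if not res.success:
            converged = False
            flags.append("rho_search_failed")
        rho_hat = float(res.x)
        if abs(rho_hat) >= RHO_BOUND - 1e-3:
            flags.append("rho_at_bound")
        beta, rss, _, _ = _gls_at_rho(y, X, rho_hat)
        sigma_u = math.sqrt(rss / (n - p))
        ll_reml = reml_profile(y, X, rho_hat)
        ll_ml = _ml_loglik(y, X, rho_hat)
        aic = -2.0 * ll_ml + 2.0 * (p + 2)  # + rho and sigma_u

    a0, harmonics, spline = _unpack(beta, design)
    if "degenerate" in flags:
        # constant pixel: the lstsq solution spreads machine noise over the
        # columns; report an exact zero wave instead
        harmonics = tuple((0.0, 0.0) for _ in harmonics)
        spline = (0.0, 0.0, 0.0, 0.0)
        a0 = float(np.mean(y))
    fit = HarmonicFit(
        a0=a0, harmonics=harmonics, spline=spline,
        rho=rho_hat, sigma_u=sigma_u,
        loglik_reml=ll_reml, loglik_ml=ll_ml, aic=aic,
        hrw_amplitude=0.0, time_to_trough=float("nan"),
        basis=basis, converged=converged, flags=tuple(flags),
    )
    amp = hrw_amplitude(fit)
    # a wave at numerical-noise scale relative to the data is no wave: its
    # trough location would be meaningless
    if amp <= 1e-10 * max(1.0, math.sqrt(scale)):
        amp = 0.0
        if "perfect_fit" in flags and "degenerate" not in flags:
            fit.flags = tuple([*fit.flags, "zero_amplitude"])
    fit.hrw_amplitude = amp
    fit.time_to_trough = time_to_trough(fit) if amp > 0 else float("nan")
    return fit


def periodic_component(fit: HarmonicFit, t) -> np.ndarray | float:
    """Fitted periodic pulse component at time(s) ``t`` (a0/drift excluded)."""
    t = np.asarray(t, dtype=float)
    w = fit.omega
    out = np.zeros_like(t)
    for n, (a, b) in enumerate(fit.harmonics, start=1):
        out = out + a * np.cos(w * n * t) + b * np.sin(w * n * t)
    return out if out.ndim else float(out)


def _extremum(fit: HarmonicFit, sign: float):
    """(location, value) of the min (sign=+1) or max (sign=-1) of the
    periodic component on [0, 1), by dense grid plus bounded refinement."""
    grid = np.linspace(0.0, 1.0, _TROUGH_GRID, endpoint=False)
    vals = sign * periodic_component(fit, grid)
    i = int(np.argmin(vals))
    h = 1.0 / _TROUGH_GRID
    lo, hi = grid[i] - h, grid[i] + h
    res = minimize_scalar(
        lambda x: sign * float(periodic_component(fit, x)),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
    )
    x = float(res.x) % 1.0
    v = sign * float(res.fun)
    # ties broken by smallest t: keep the grid point if refinement only
    # matched the same value elsewhere
    if sign * v > vals[i]:
        x, v = float(grid[i]), sign * float(vals[i])
    return x, v


def hrw_amplitude(fit: HarmonicFit) -> float:
    """Harmonic regression wave amplitude: peak-to-trough range of the
    periodic component over one cycle. Invariant to a0 and spline terms."""
    if all(a == 0.0 and b == 0.0 for a, b in fit.harmonics):
        return 0.0
    _, vmin = _extremum(fit, +1.0)
    _, vmax = _extremum(fit, -1.0)
    return max(vmax - vmin, 0.0)


def time_to_trough(fit: HarmonicFit) -> float:
    """Location of the periodic component's minimum on [0, 1), in cycle
    fractions; t = 0 is the oximetry-synchronized cycle start. NaN when the
    wave has zero amplitude (trough undefined)."""
    if hrw_amplitude(fit) == 0.0:
        return float("nan")
    x, _ = _extremum(fit, +1.0)
    return x % 1.0


def select_order_aic(
    series: PixelSeries,
    max_order: int = 4,
    knots: tuple[float, ...] | None = None,
    basis: str = "2pi",
) -> int:
    """Harmonic order minimizing AIC among 1..max_order.

    AIC is computed from the full ML log-likelihood with parameter count
    equal to the regression coefficients plus two (rho, sigma_u); REML
    likelihoods are not comparable across fixed-effect structures.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    best_order, best_aic = None, np.inf
    errors = []
    for k in range(1, max_order + 1):
        try:
            fit = fit_harmonic_regression(series, order=k, knots=knots, basis=basis)
        except FitError as exc:
            errors.append(exc)
            continue
        if fit.aic < best_aic:
            best_order, best_aic = k, fit.aic
    if best_order is None:
        raise FitError(f"all candidate orders failed: {errors}")
    return best_order
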