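"""The transformed inverse Weibull distribution (TIWD).

The TIWD arises from the inverse Weibull CDF ``G(x) = exp(-x^(-beta))``
(scale fixed at 1) through the transform ``F = exp(alpha * (1 - 1/G))``,
giving

    F(x; alpha, beta) = exp(alpha * (1 - e^(x^(-beta)))),       x > 0,
    f(x; alpha, beta) = alpha*beta * x^(-beta-1)
                        * exp(alpha*(1 - e^(x^(-beta)))) * e^(x^(-beta)),

with two positive shape parameters.  The survival function decays
algebraically, ``S(x) ~ alpha * x^(-beta)`` as ``x -> inf``, so the
distribution is heavy tailed and the r-th moment is finite iff ``r < beta``.

All tail-sensitive integrals (normalization, moments, mean residual life)
are evaluated after the probability substitution ``x = rho(w)``,
``w in (0, 1)``, where ``rho`` is the quantile function; along that path

    log f(rho(w)) = log(alpha*beta) + ((beta+1)/beta) * log(u) + log(w) + u,
    u(w) = log1p(-log(w)/alpha),

which is exact and never exponentiates a large ``x^(-beta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "TiwdParams",
    "LifetimeSample",
    "MomentOrder",
    "TransformedInverseWeibull",
    "InfiniteMomentError",
]

# exp(t) overflows IEEE doubles near t = 709; beyond this every formula
# switches to a log-space or shifted evaluation.
_EXP_OVERFLOW = 700.0


class InfiniteMomentError(ValueError):
    """Raised when a moment of order r >= beta is requested (r < beta required)."""


@dataclass(frozen=True)
class TiwdParams:
    """The pair (alpha, beta) of positive shape parameters."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float, np.floating, np.integer))):
                raise TypeError(f"{name} must be a real number, got {v!r}")
            v = float(v)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
            object.__setattr__(self, name, v)


class LifetimeSample:
    """An ordered collection of strictly positive lifetime observations."""

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("a lifetime sample needs at least one observation")
        bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
        if bad.size:
            raise ValueError(
                f"nonpositive or non-finite value {arr[bad[0]]!r} at row {bad[0] + 1}"
            )
        self.values = arr
        self.n = int(arr.size)
        self._sorted: np.ndarray | None = None

    @property
    def sorted_values(self) -> np.ndarray:
        if self._sorted is None:
            self._sorted = np.sort(self.values)
        return self._sorted

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)

    def __repr__(self) -> str:
        return f"LifetimeSample(n={self.n}, min={self.values.min()}, max={self.values.max()})"


@dataclass(frozen=True)
class MomentOrder:
    """Order r > 0 of a (possibly incomplete) moment."""

    r: float

    def __post_init__(self) -> None:
        if not (float(self.r) > 0 and math.isfinite(float(self.r))):
            raise ValueError(f"moment order must be finite and > 0, got {self.r}")
        object.__setattr__(self, "r", float(self.r))


def _as_params(params) -> TiwdParams:
    if isinstance(params, TiwdParams):
        return params
    if isinstance(params, (tuple, list)) and len(params) == 2:
        return TiwdParams(*params)
    raise TypeError(f"expected TiwdParams or (alpha, beta) pair, got {params!r}")


def _check_positive_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("x must be strictly positive")
    return x


@dataclass
class ReliabilityCurves:
    sf: np.ndarray | float
    hazard: np.ndarray | float
    cum_hazard: np.ndarray | float
    reversed_hazard: np.ndarray | float


@dataclass
class ShapeMeasures:
    bowley_skewness: float
    moors_kurtosis: float


@dataclass
class LorenzBonferroni:
    L: np.ndarray | float
    B: np.ndarray | float


@dataclass
class TailDiagnostics:
    x_grid: np.ndarray
    etx_S_values: np.ndarray
    log_etx_S: np.ndarray
    pareto_ratio: np.ndarray


class TransformedInverseWeibull:
    """A frozen TIWD with parameters ``(alpha, beta)``.

    Exposes the usual d/p/q/r surface (``pdf``/``cdf``/``ppf``/``rvs``) plus
    reliability curves, moments, inequality curves, order statistics and
    tail diagnostics.
    """

    def __init__(self, alpha: float, beta: float):
        self.params = TiwdParams(alpha, beta)

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta

    # -- densities and distribution functions ------------------------------

    def _t(self, x: np.ndarray) -> np.ndarray:
        """t = x^(-beta), computed as exp(-beta*log x) (inf on underflowing x)."""
        with np.errstate(over="ignore"):
            return np.exp(-self.beta * np.log(x))

    def log_pdf(self, x):
        x = _check_positive_x(x)
        t = self._t(x)
        with np.errstate(over="ignore", invalid="ignore"):
            out = (
                math.log(self.alpha * self.beta)
                - (self.beta + 1.0) * np.log(x)
                - self.alpha * np.expm1(t)
                + t
            )
        # t = inf means x so small that the density underflows to 0
        return np.where(np.isfinite(t), out, -np.inf)[()] if np.ndim(out) else float(out)

    def pdf(self, x):
        return np.exp(self.log_pdf(x))

    def log_cdf(self, x):
        x = _check_positive_x(x)
        t = self._t(x)
        with np.errstate(over="ignore"):
            out = -self.alpha * np.expm1(t)
        return np.where(np.isfinite(t), out, -np.inf)[()] if np.ndim(out) else float(out)

    def cdf(self, x):
        return np.exp(self.log_cdf(x))

    def log_sf(self, x):
        logF = np.asarray(self.log_cdf(x), dtype=float)
        # S = -expm1(logF); near logF = 0 use log(-logF)-style expansion via
        # log(-expm1(z)) which is exact for z in (-inf, 0).
        with np.errstate(divide="ignore"):
            out = np.log(-np.expm1(logF))
        return out[()] if np.ndim(out) else float(out)

    def sf(self, x):
        logF = np.asarray(self.log_cdf(x), dtype=float)
        out = -np.expm1(logF)
        return out[()] if np.ndim(out) else float(out)

    def reliability_curves(self, x) -> ReliabilityCurves:
        """Survival, hazard, cumulative hazard and reversed hazard at x.

        The reversed hazard f/F simplifies analytically to
        ``alpha*beta*x^(-beta-1)*e^(x^(-beta))`` (the shared exponential
        factor cancels); the hazard is evaluated in log space so that sf
        underflow never produces NaN.
        """
        x = _check_positive_x(x)
        t = self._t(x)
        log_sf = np.asarray(self.log_sf(x), dtype=float)
        log_hazard = np.asarray(self.log_pdf(x), dtype=float) - log_sf
        with np.errstate(over="ignore"):
            log_rev = math.log(self.alpha * self.beta) - (self.beta + 1.0) * np.log(x) + t
        sq = lambda a: a[()] if np.ndim(x) else float(a)
        return ReliabilityCurves(
            sf=sq(np.asarray(self.sf(x))),
            hazard=sq(np.exp(log_hazard)),
            cum_hazard=sq(-log_sf),
            reversed_hazard=sq(np.exp(log_rev)),
        )

    # -- quantiles and sampling --------------------------------------------

    def ppf(self, w):
        """Quantile function rho(w) = [log1p(-log(w)/alpha)]^(-1/beta)."""
        w = np.asarray(w, dtype=float)
        if np.any(~((w > 0) & (w < 1))):
            raise ValueError("probability must lie strictly in (0, 1)")
        u = np.log1p(-np.log(w) / self.alpha)
        out = u ** (-1.0 / self.beta)
        return out[()] if np.ndim(out) else float(out)

    quantile = ppf

    def isf(self, s):
        """Inverse survival function, accurate for s near 0 (w = 1 - s)."""
        s = np.asarray(s, dtype=float)
        if np.any(~((s > 0) & (s < 1))):
            raise ValueError("probability must lie strictly in (0, 1)")
        u = np.log1p(-np.log1p(-s) / self.alpha)
        out = u ** (-1.0 / self.beta)
        return out[()] if np.ndim(out) else float(out)

    def rvs(self, n: int, seed=None) -> LifetimeSample:
        """n i.i.d. draws by inverse-transform sampling."""
        if not (int(n) >= 1):
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        w = rng.uniform(size=int(n))
        # uniform(0,1) excludes 1 but can hit 0 in principle; nudge exact zeros
        w[w == 0.0] = np.nextafter(0.0, 1.0)
        return LifetimeSample(self.ppf(w))

    sample = rvs

    # -- substitution helpers ----------------------------------------------

    def _u_of_w(self, w):
        return np.log1p(-np.log(w) / self.alpha)

    def log_pdf_at_quantile(self, w):
        """log f(rho(w)) along the probability substitution (exact algebra)."""
        u = self._u_of_w(np.asarray(w, dtype=float))
        return (
            math.log(self.alpha * self.beta)
            + (self.beta + 1.0) / self.beta * np.log(u)
            + np.log(w)
            + u
        )

    # -- moments -------------------------------------------------------------

    def raw_moment(self, r) -> float:
        """r-th raw moment; finite iff r < beta (heavy-tail constraint)."""
        r = r.r if isinstance(r, MomentOrder) else float(r)
        if r <= 0:
            raise ValueError("moment order must be > 0")
        if r >= self.beta:
            raise InfiniteMomentError(
                f"the moment of order r={r} is infinite: the TIWD has "
                f"S(x) ~ alpha*x^(-beta), so moments require r < beta (beta={self.beta})"
            )
        val, err = integrate.quad(
            lambda w: self._u_of_w(w) ** (-r / self.beta), 0.0, 1.0,
            limit=200, points=[1.0 - 1e-12],
        )
        return val

    def mean(self) -> float:
        return self.raw_moment(1.0)

    def var(self) -> float:
        m1 = self.raw_moment(1.0)
        m2 = self.raw_moment(2.0)
        return m2 - m1 * m1

    def incomplete_moment(self, r, x) -> float:
        """I_r(x) = int_0^x s^r f(s) ds, via the probability substitution."""
        r = r.r if isinstance(r, MomentOrder) else float(r)
        if r >= self.beta:
            raise InfiniteMomentError(
                f"incomplete moments are only defined here for r < beta "
                f"(r={r}, beta={self.beta})"
            )
        x = float(x)
        if x <= 0:
            raise ValueError("x must be strictly positive")
        w_hi = self.cdf(x)
        if w_hi <= 0.0:
            return 0.0
        val, err = integrate.quad(
            lambda w: self._u_of_w(w) ** (-r / self.beta), 0.0, w_hi, limit=200,
        )
        return val

    def lorenz_bonferroni(self, x) -> LorenzBonferroni:
        """Lorenz curve L(x) = I_1(x)/mu and Bonferroni curve B = L/F."""
        if self.beta <= 1.0:
            raise InfiniteMomentError(
                "the Lorenz curve needs a finite mean, i.e. beta > 1 "
                f"(beta={self.beta})"
            )
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        mu = self.mean()
        L = np.array([self.incomplete_moment(1.0, xi) / mu for xi in xs])
        B = L / self.cdf(xs)
        if np.ndim(x) == 0:
            return LorenzBonferroni(L=float(L[0]), B=float(B[0]))
        return LorenzBonferroni(L=L, B=B)

    def mean_residual_life(self, x) -> float:
        """m(x) = E[X - x | X > x] = int_x^inf S(y) dy / S(x); needs beta > 1."""
        if self.beta <= 1.0:
            raise InfiniteMomentError(
                "the mean residual life diverges unless the mean exists "
                f"(requires beta > 1; beta={self.beta}; moments need r < beta)"
            )
        x = float(x)
        if x <= 0:
            raise ValueError("x must be strictly positive")
        # int_x^inf S dy = E[(X - x)+] = int_{F(x)}^1 (rho(w) - x) dw.
        # Near w = 1 the integrand blows up like (1-w)^(-1/beta); the change
        # of variable 1 - w = u^p with p = beta/(beta-1) makes it smooth.
        s0 = self.sf(x)
        p = self.beta / (self.beta - 1.0)
        u_top = s0 ** (1.0 / p)
        s_floor = 1e-300

        def integrand(u):
            s = max(u ** p, s_floor)
            return (self.isf(s) - x) * p * u ** (p - 1.0)

        tail, err = integrate.quad(integrand, 0.0, u_top, limit=300,
                                   epsabs=1e-12, epsrel=1e-12)
        return tail / s0

    # -- order statistics ----------------------------------------------------

    def order_statistic_pdf(self, j: int, n: int, x):
        """Density of the j-th of n order statistics."""
        j, n = int(j), int(n)
        if not (1 <= j <= n):
            raise ValueError(f"need 1 <= j <= n, got j={j}, n={n}")
        x = _check_positive_x(x)
        logF = np.asarray(self.log_cdf(x), dtype=float)
        log_sf = np.asarray(self.log_sf(x), dtype=float)
        logf = np.asarray(self.log_pdf(x), dtype=float)
        # n!/((j-1)!(n-j)!) = 1/B(j, n-j+1)
        log_coef = -special.betaln(j, n - j + 1)
        out = np.exp(log_coef + logf + (j - 1) * logF + (n - j) * log_sf)
        return out[()] if np.ndim(out) else float(out)

    # -- shape and tail ------------------------------------------------------

    def shape_measures(self) -> ShapeMeasures:
        """Quantile-based Bowley skewness and Moors kurtosis."""
        q = self.ppf
        s = (q(0.75) + q(0.25) - 2.0 * q(0.5)) / (q(0.75) - q(0.25))
        k = (q(7 / 8) - q(5 / 8) + q(3 / 8) - q(1 / 8)) / (q(6 / 8) - q(2 / 8))
        return ShapeMeasures(bowley_skewness=s, moors_kurtosis=k)

    def tail_diagnostics(self, t: float, x_grid) -> TailDiagnostics:
        """Heavy-tail checks: e^(t x) S(x) (eventually increasing for any t>0)
        and the Pareto ratio S(x) / (alpha x^(-beta)) -> 1."""
        t = float(t)
        if t <= 0:
            raise ValueError("t must be > 0")
        x = _check_positive_x(x_grid)
        log_sf = np.asarray(self.log_sf(x), dtype=float)
        log_etx_S = t * x + log_sf
        with np.errstate(over="ignore"):
            etx = np.exp(log_etx_S)
        ratio = np.exp(log_sf - math.log(self.alpha) + self.beta * np.log(x))
        return TailDiagnostics(x_grid=x, etx_S_values=etx, log_etx_S=log_etx_S,
                               pareto_ratio=ratio)

    # -- misc ----------------------------------------------------------------

    def loglik(self, sample: LifetimeSample) -> float:
        """Complete-sample log-likelihood at these parameters."""
        x = sample.values if isinstance(sample, LifetimeSample) else np.asarray(sample)
        return float(np.sum(self.log_pdf(x)))

    def ks_self_test(self, n: int = 100_000, seed=0):
        """One-sample KS test of n inverse-transform draws against the CDF."""
        draws = self.rvs(n, seed=seed)
        return stats.kstest(draws.values, self.cdf)

    def __repr__(self) -> str:
        return f"TransformedInverseWeibull(alpha={self.alpha!r}, beta={self.beta!r})"
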