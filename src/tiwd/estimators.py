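"""Frequentist fitting of the TIWD.

Maximum likelihood reduces to one-dimensional root finding: the alpha score
has the closed-form solution ``alpha(beta) = n / sum(e^(x_i^-beta) - 1)``
(strictly decreasing in alpha, so unique), and substituting it into the beta
score leaves a profiled score that changes sign exactly once on (0, inf).
The root is bracketed on [1e-3, 64] with geometric expansion and solved by
bisection-style root finding.

The three minimum-distance estimators minimize the Anderson-Darling,
Cramer-von-Mises and ordinary-least-squares discrepancies between the model
CDF and the empirical CDF, by multistart quasi-Newton descent on
(log alpha, log beta) (positivity without constraints), seeded at the ML
estimate plus perturbed starts.

The scikit-learn estimator surface lives in :class:`TIWDFitter`; the
module-level ``ml_fit``/``ad_fit``/``cvm_fit``/``ols_fit`` functions are
thin wrappers over it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .distribution import (
    LifetimeSample,
    TiwdParams,
    TransformedInverseWeibull,
)

__all__ = [
    "FitResult",
    "FisherInfo",
    "ConfidenceInterval",
    "TIWDFitter",
    "profile_alpha",
    "score_alpha",
    "score_beta",
    "profile_score_beta",
    "loglik",
    "ml_fit",
    "ad_fit",
    "cvm_fit",
    "ols_fit",
    "fisher_information",
    "asymptotic_ci",
    "distance_partials",
    "ad_objective",
    "cvm_objective",
    "ols_objective",
    "ConvergenceError",
]

_METHODS = ("ml", "ad", "cvm", "ols")
_SHIFT = 500.0  # above this, e^(x^-beta) terms are evaluated in shifted form


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    params: TiwdParams
    loglik: float
    method: str
    objective: float | None = None
    converged: bool = True
    iterations: int = 0
    gradient_norm: float = float("nan")

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta

    def distribution(self) -> TransformedInverseWeibull:
        return TransformedInverseWeibull(self.params.alpha, self.params.beta)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "loglik": self.loglik,
            "objective": self.objective,
            "converged": self.converged,
            "iterations": self.iterations,
            "gradient_norm": self.gradient_norm,
        }


@dataclass
class FisherInfo:
    info_matrix: np.ndarray
    covariance: np.ndarray

    @property
    def var_alpha(self) -> float:
        return float(self.covariance[0, 0])

    @property
    def var_beta(self) -> float:
        return float(self.covariance[1, 1])


@dataclass
class ConfidenceInterval:
    level: float
    theta: float
    lower: float
    upper: float
    z: float


def _as_sample(sample) -> LifetimeSample:
    return sample if isinstance(sample, LifetimeSample) else LifetimeSample(sample)


# ---------------------------------------------------------------------------
# likelihood machinery

def loglik(params, sample) -> float:
    """Complete-sample TIWD log-likelihood
    n log(alpha beta) - (beta+1) sum log x + alpha sum(1-e^(x^-beta)) + sum x^-beta."""
    s = _as_sample(sample)
    p = params if isinstance(params, TiwdParams) else TiwdParams(*params)
    return TransformedInverseWeibull(p.alpha, p.beta).loglik(s)


def _t_and_shift(beta: float, logx: np.ndarray):
    """t_i = x_i^-beta and a shifted weight exp(t_i - m) safe against overflow."""
    t = np.exp(-beta * logx)
    m = float(np.max(t))
    return t, m


def profile_alpha(beta: float, sample) -> float:
    """Closed-form alpha solving the alpha score: alpha = n / sum(e^(x_i^-beta)-1)."""
    s = _as_sample(sample)
    logx = np.log(s.values)
    t, m = _t_and_shift(float(beta), logx)
    if not np.all(np.isfinite(t)):
        return 0.0  # denominator is +inf
    if m <= _SHIFT:
        denom = float(np.sum(np.expm1(t)))
        return s.n / denom
    # sum expm1(t) = e^m * sum(exp(t-m) - e^-m)
    w = np.exp(t - m)
    denom_shifted = float(np.sum(w - math.exp(-m)))
    return s.n * math.exp(-m) / denom_shifted


def score_alpha(alpha: float, beta: float, sample) -> float:
    """p(alpha) = n/alpha + sum(1 - e^(x_i^-beta)); strictly decreasing in alpha."""
    s = _as_sample(sample)
    t = np.exp(-float(beta) * np.log(s.values))
    with np.errstate(over="ignore"):
        out = s.n / float(alpha) - float(np.sum(np.expm1(t)))
    return out


def score_beta(beta: float, sample, alpha: float) -> float:
    """The beta score
    p(beta) = n/beta - sum log x + alpha sum e^(x^-beta) x^-beta log x - sum x^-beta log x."""
    s = _as_sample(sample)
    beta, alpha = float(beta), float(alpha)
    logx = np.log(s.values)
    t, m = _t_and_shift(beta, logx)
    if not np.all(np.isfinite(t)):
        return -np.inf
    if m <= _SHIFT:
        cross = float(np.sum(np.exp(t) * t * logx))
    else:
        with np.errstate(over="ignore"):
            cross = math.exp(m) * float(np.sum(np.exp(t - m) * t * logx))
    val = (
        s.n / beta
        - float(np.sum(logx))
        + alpha * cross
        - float(np.sum(t * logx))
    )
    return val if np.isfinite(val) else -np.inf


def profile_score_beta(beta: float, sample) -> float:
    """Beta score with alpha profiled out; the 1-D function whose unique root
    is the ML estimate.  Evaluated in a shifted form so that the
    alpha(beta) * sum e^t t log x product never overflows."""
    s = _as_sample(sample)
    beta = float(beta)
    logx = np.log(s.values)
    t, m = _t_and_shift(beta, logx)
    base = s.n / beta - float(np.sum(logx)) - float(np.sum(np.where(np.isfinite(t), t * logx, 0.0)))
    if not np.all(np.isfinite(t)):
        return -np.inf  # some x < 1 with beta huge: score -> -inf (all mass at e^t)
    if m <= _SHIFT:
        denom = float(np.sum(np.expm1(t)))
        cross = float(np.sum(np.exp(t) * t * logx))
    else:
        w = np.exp(t - m)
        denom = float(np.sum(w - math.exp(-m)))
        cross = float(np.sum(w * t * logx))
    val = base + s.n * cross / denom
    return val if np.isfinite(val) else -np.inf


def _bracket_profile_root(sample, lo=1e-3, hi=64.0, max_hi=1024.0):
    f_lo = profile_score_beta(lo, sample)
    f_hi = profile_score_beta(hi, sample)
    scanned = [(lo, f_lo), (hi, f_hi)]
    while f_lo * f_hi > 0 and hi < max_hi:
        hi *= 2.0
        f_hi = profile_score_beta(hi, sample)
        scanned.append((hi, f_hi))
    while f_lo * f_hi > 0 and lo > 1e-8:
        lo /= 2.0
        f_lo = profile_score_beta(lo, sample)
        scanned.append((lo, f_lo))
    if f_lo * f_hi > 0:
        raise ConvergenceError(
            f"no sign change of the profiled beta score on the scanned bracket {scanned}"
        )
    return lo, hi


def ml_fit(sample, return_fisher: bool = False):
    """Maximum-likelihood fit by profiling alpha and root-finding the beta score."""
    s = _as_sample(sample)
    if s.n < 2:
        raise ValueError("maximum likelihood needs n >= 2")
    lo, hi = _bracket_profile_root(s)
    sol = optimize.root_scalar(
        profile_score_beta, args=(s,), bracket=(lo, hi), method="brentq",
        xtol=1e-12, rtol=8.881784197001252e-16,
    )
    beta_hat = sol.root
    alpha_hat = profile_alpha(beta_hat, s)
    params = TiwdParams(alpha_hat, beta_hat)
    grad = np.array([
        score_alpha(alpha_hat, beta_hat, s),
        score_beta(beta_hat, s, alpha_hat),
    ])
    result = FitResult(
        params=params,
        loglik=loglik(params, s),
        method="ml",
        objective=None,
        converged=bool(sol.converged),
        iterations=int(sol.iterations),
        gradient_norm=float(np.linalg.norm(grad)),
    )
    if return_fisher:
        return result, fisher_information(params, s)
    return result


def fisher_information(params, sample) -> FisherInfo:
    """Observed Fisher information (negative Hessian of the log-likelihood),
    from the analytic second derivatives, with its 2x2 inverse."""
    p = params if isinstance(params, TiwdParams) else TiwdParams(*params)
    s = _as_sample(sample)
    a, b = p.alpha, p.beta
    logx = np.log(s.values)
    t = np.exp(-b * logx)
    et = np.exp(t)
    d2_aa = -s.n / a**2
    d2_ab = float(np.sum(et * t * logx))
    d2_bb = (
        -s.n / b**2
        - a * float(np.sum(et * t * logx**2 * (t + 1.0)))
        + float(np.sum(t * logx**2))
    )
    info = -np.array([[d2_aa, d2_ab], [d2_ab, d2_bb]])
    det = info[0, 0] * info[1, 1] - info[0, 1] * info[1, 0]
    if det == 0 or not np.isfinite(det):
        raise ConvergenceError("singular Fisher information matrix")
    cov = np.array([[info[1, 1], -info[0, 1]], [-info[1, 0], info[0, 0]]]) / det
    return FisherInfo(info_matrix=info, covariance=cov)


def asymptotic_ci(fit: FitResult, info: FisherInfo, theta: float = 0.05):
    """Normal asymptotic confidence intervals estimate +/- z_(theta/2) * se.

    Lower bounds may be negative; no truncation at zero is applied.
    """
    theta = float(theta)
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - theta / 2.0)
    out = []
    for est, var in ((fit.alpha, info.var_alpha), (fit.beta, info.var_beta)):
        half = z * math.sqrt(var)
        out.append(ConfidenceInterval(level=1.0 - theta, theta=theta,
                                      lower=est - half, upper=est + half, z=z))
    return tuple(out)


# ---------------------------------------------------------------------------
# minimum-distance estimation

def distance_partials(x, params):
    """Partials of the CDF: theta1 = dF/dalpha = F*(1-e^(x^-beta)),
    theta2 = dF/dbeta = alpha x^-beta e^(x^-beta) F log x."""
    p = params if isinstance(params, TiwdParams) else TiwdParams(*params)
    d = TransformedInverseWeibull(p.alpha, p.beta)
    x = np.asarray(x, dtype=float)
    t = np.exp(-p.beta * np.log(x))
    F = d.cdf(x)
    theta1 = -F * np.expm1(t)
    with np.errstate(over="ignore"):
        theta2 = p.alpha * t * np.exp(t) * F * np.log(x)
    sq = lambda a: a[()] if np.ndim(x) else float(a)
    return {"theta1": sq(theta1), "theta2": sq(theta2)}


def _log_cdfs(params, xs: np.ndarray):
    d = TransformedInverseWeibull(params[0], params[1])
    return np.asarray(d.log_cdf(xs)), np.asarray(d.log_sf(xs))


def ad_objective(params, sample) -> float:
    """Anderson-Darling criterion
    A = -n - (1/n) sum (2i-1)[log F(x_(i)) + log(1 - F(x_(n+1-i)))]."""
    s = _as_sample(sample)
    xs = s.sorted_values
    logF, logS = _log_cdfs(params, xs)
    i = np.arange(1, s.n + 1)
    return float(-s.n - np.sum((2 * i - 1) * (logF + logS[::-1])) / s.n)


def cvm_objective(params, sample) -> float:
    """Cramer-von-Mises criterion C = 1/(12n) + sum (F(x_(i)) - (2i-1)/(2n))^2."""
    s = _as_sample(sample)
    xs = s.sorted_values
    F = TransformedInverseWeibull(params[0], params[1]).cdf(xs)
    i = np.arange(1, s.n + 1)
    return float(1.0 / (12.0 * s.n) + np.sum((F - (2 * i - 1) / (2.0 * s.n)) ** 2))


def ols_objective(params, sample, plotting_position: str = "standard") -> float:
    """Least-squares criterion L = sum (F(x_(i)) - p_i)^2 with plotting
    position p_i = i/(n+1) ("standard") or p_i = i/(n+i) ("paper")."""
    s = _as_sample(sample)
    xs = s.sorted_values
    F = TransformedInverseWeibull(params[0], params[1]).cdf(xs)
    i = np.arange(1, s.n + 1)
    if plotting_position == "standard":
        p = i / (s.n + 1.0)
    elif plotting_position == "paper":
        p = i / (s.n + i.astype(float))
    else:
        raise ValueError("plotting_position must be 'standard' or 'paper'")
    return float(np.sum((F - p) ** 2))


def _distance_gradient(params, sample, kind: str, plotting_position="standard"):
    """Analytic gradient of the distance objective in (alpha, beta)."""
    s = _as_sample(sample)
    xs = s.sorted_values
    n = s.n
    i = np.arange(1, n + 1)
    pp = distance_partials(xs, TiwdParams(*params))
    th = np.vstack([pp["theta1"], pp["theta2"]])
    d = TransformedInverseWeibull(params[0], params[1])
    F = np.asarray(d.cdf(xs))
    if kind == "ad":
        S_rev = np.asarray(d.sf(xs))[::-1]
        th_rev = th[:, ::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = th / np.maximum(F, 1e-300) - th_rev / np.maximum(S_rev, 1e-300)
        return -(terms @ (2 * i - 1)) / n
    if kind == "cvm":
        resid = F - (2 * i - 1) / (2.0 * n)
    elif kind == "ols":
        if plotting_position == "standard":
            resid = F - i / (n + 1.0)
        else:
            resid = F - i / (n + i.astype(float))
    else:
        raise ValueError(kind)
    return 2.0 * (th @ resid)


def _minimize_distance(sample, kind: str, plotting_position="standard",
                       n_starts: int = 9, seed: int = 0):
    s = _as_sample(sample)
    if s.n < 2:
        raise ValueError("distance estimation needs n >= 2")
    if kind == "ad":
        obj = lambda p: ad_objective(p, s)
    elif kind == "cvm":
        obj = lambda p: cvm_objective(p, s)
    else:
        obj = lambda p: ols_objective(p, s, plotting_position)

    def obj_log(z):
        with np.errstate(over="ignore", invalid="ignore"):
            val = obj(np.exp(z))
        return val if np.isfinite(val) else 1e300

    try:
        ml = ml_fit(s)
        center = np.log([ml.alpha, ml.beta])
    except ConvergenceError:
        center = np.array([0.0, 0.0])
    rng = np.random.default_rng(seed)
    starts = [center] + [center + rng.normal(scale=0.5, size=2)
                         for _ in range(n_starts - 1)]
    best = None
    for z0 in starts:
        res = optimize.minimize(obj_log, z0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            f"{kind} optimizer failed from all {n_starts} starts"
        )
    params = TiwdParams(*np.exp(best.x))
    grad = _distance_gradient((params.alpha, params.beta), s, kind, plotting_position)
    return FitResult(
        params=params,
        loglik=loglik(params, s),
        method=kind,
        objective=float(best.fun),
        converged=bool(best.success),
        iterations=int(best.nit),
        gradient_norm=float(np.linalg.norm(grad)),
    )


def ad_fit(sample, seed: int = 0) -> FitResult:
    """Minimum Anderson-Darling distance estimate."""
    return _minimize_distance(sample, "ad", seed=seed)


def cvm_fit(sample, seed: int = 0) -> FitResult:
    """Minimum Cramer-von-Mises distance estimate."""
    return _minimize_distance(sample, "cvm", seed=seed)


def ols_fit(sample, plotting_position: str = "standard", seed: int = 0) -> FitResult:
    """Ordinary least squares on the CDF at plotting positions."""
    return _minimize_distance(sample, "ols", plotting_position=plotting_position,
                              seed=seed)


# ---------------------------------------------------------------------------
# scikit-learn estimator surface

class TIWDFitter(BaseEstimator):
    """Fit a TIWD to univariate positive data (scikit-learn estimator).

    Parameters
    ----------
    method : {"ml", "ad", "cvm", "ols"}, default "ml"
        Estimation principle: maximum likelihood, minimum Anderson-Darling,
        minimum Cramer-von-Mises, or least squares on plotting positions.
    plotting_position : {"standard", "paper"}, default "standard"
        OLS target probabilities: i/(n+1) or i/(n+i) (only used by "ols").
    random_state : int, default 0
        Seed for the multistart perturbations of the distance optimizers.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted shape parameters.
    loglik_ : float
        Log-likelihood at the fitted parameters.
    result_ : FitResult
        Full convergence record.
    fisher_information_ : FisherInfo
        Observed information and covariance (method="ml" only).
    """

    def __init__(self, method: str = "ml", plotting_position: str = "standard",
                 random_state: int = 0):
        self.method = method
        self.plotting_position = plotting_position
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        sample = _as_sample(np.asarray(X, dtype=float).ravel())
        if self.method == "ml":
            result, info = ml_fit(sample, return_fisher=True)
            self.fisher_information_ = info
        elif self.method == "ad":
            result = ad_fit(sample, seed=self.random_state)
        elif self.method == "cvm":
            result = cvm_fit(sample, seed=self.random_state)
        else:
            result = ols_fit(sample, plotting_position=self.plotting_position,
                             seed=self.random_state)
        self.result_ = result
        self.alpha_ = result.alpha
        self.beta_ = result.beta
        self.loglik_ = result.loglik
        self.n_samples_ = sample.n
        self.distribution_ = result.distribution()
        return self

    def score_samples(self, X):
        """Per-observation log-density under the fitted TIWD."""
        return np.asarray(self.distribution_.log_pdf(np.asarray(X, dtype=float).ravel()))

    def score(self, X, y=None):
        """Total log-likelihood of X under the fitted TIWD."""
        return float(np.sum(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None):
        return self.distribution_.rvs(n_samples, seed=random_state).values

    def confidence_intervals(self, theta: float = 0.05):
        """Asymptotic normal CIs for (alpha, beta); method='ml' only."""
        if not hasattr(self, "fisher_information_"):
            raise AttributeError("confidence intervals need a method='ml' fit")
        return asymptotic_ci(self.result_, self.fisher_information_, theta)
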