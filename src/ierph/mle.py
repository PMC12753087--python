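"""Maximum-likelihood inference for the IER model under PHT-ICS.

With ``r`` observed failures x_1 < ... < x_r, per-failure removals R_i,
termination point C and terminal removal R_T, the log-likelihood is

    ln L = r ln(theta) + r ln(lam) - lam * sum(x_i^-2)
           + sum([theta*(1+R_i) - 1] * ln(1 - e^{-lam x_i^-2}))
           + theta * R_T * ln(1 - e^{-lam C^-2}).

The shape profiles out in closed form, theta(lam) = r / Q(lam) with

    Q(lam) = -[ sum((1+R_i) ln(1 - e^{-lam x_i^-2})) + R_T ln(1 - e^{-lam C^-2}) ],

so the fit reduces to a one-dimensional root solve of the profiled score in
``lam`` (bracketed bisection/Brent), with a 2-D Nelder-Mead fall-back in
log-parameter space when bracketing fails.  Standard errors come from the
inverse of the closed-form observed information; intervals for R(x) and H(x)
use the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import model
from .censoring import PHTICSample
from .model import IERParams, log1mexp

__all__ = [
    "FitResult",
    "ConfidenceInterval",
    "DeltaGradient",
    "log_likelihood",
    "score",
    "profile_theta",
    "fit_mle",
    "observed_info",
    "aci_normal",
    "aci_lognormal",
    "estimate_rh",
    "rh_gradients",
    "delta_variance",
]


@dataclass(frozen=True)
class FitResult:
    """Point estimates with observed-information covariance."""

    theta_hat: float
    lam_hat: float
    loglik: float
    cov: np.ndarray  # 2x2, order (theta, lam)
    method: str  # "MLE" or "MPS"
    converged: bool
    iterations: int

    @property
    def params(self) -> IERParams:
        return IERParams(self.theta_hat, self.lam_hat)

    @property
    def se_theta(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def se_lam(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    flavor: str  # "ACI_NA" or "ACI_NL"

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval bounds out of order")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class DeltaGradient:
    """Gradients of R(x) and H(x) in (theta, lam), for the delta method."""

    dR_dtheta: float
    dR_dlam: float
    dH_dtheta: float
    dH_dlam: float


def _sample_arrays(s: PHTICSample):
    x = s.times_array()
    removals = s.removals_array()
    return x, removals, float(s.R_T), float(s.C)


def log_likelihood(p: IERParams, s: PHTICSample) -> float:
    """Full log-likelihood, constants included (so the complete-data case
    equals the iid log-density sum)."""
    x, removals, r_t, c = _sample_arrays(s)
    r = s.r
    t = p.lam * x**-2.0
    value = (
        r * np.log(2.0 * p.theta * p.lam)
        - 3.0 * np.sum(np.log(x))
        - t.sum()
        + np.sum((p.theta * (1.0 + removals) - 1.0) * log1mexp(t))
    )
    if r_t > 0:
        value += p.theta * r_t * log1mexp(p.lam * c**-2.0)
    return float(value)


def _q_factor(lam: float, s: PHTICSample) -> float:
    """Q(lam) > 0 such that the profiled shape is theta = r / Q(lam)."""
    x, removals, r_t, c = _sample_arrays(s)
    q = -np.sum((1.0 + removals) * log1mexp(lam * x**-2.0))
    if r_t > 0:
        q -= r_t * log1mexp(lam * c**-2.0)
    return float(q)


def profile_theta(lam: float, s: PHTICSample) -> float:
    """Closed-form maximizer of the log-likelihood over theta at fixed lam."""
    if not lam > 0:
        raise ValueError("lam must be positive")
    return s.r / _q_factor(lam, s)


def score(p: IERParams, s: PHTICSample) -> np.ndarray:
    """Gradient of the log-likelihood, (d/dtheta, d/dlam)."""
    x, removals, r_t, c = _sample_arrays(s)
    r = s.r
    t = p.lam * x**-2.0
    # e^{-t} / (1 - e^{-t}), stable via log space
    w = np.exp(-t - log1mexp(t))
    d_theta = r / p.theta + np.sum((1.0 + removals) * log1mexp(t))
    d_lam = (
        r / p.lam
        - np.sum(x**-2.0)
        + np.sum((p.theta * (1.0 + removals) - 1.0) * x**-2.0 * w)
    )
    if r_t > 0:
        tc = p.lam * c**-2.0
        wc = np.exp(-tc - log1mexp(tc))
        d_theta += r_t * log1mexp(tc)
        d_lam += p.theta * r_t * c**-2.0 * wc
    return np.array([d_theta, d_lam])


def observed_info(p: IERParams, s: PHTICSample) -> np.ndarray:
    """Observed Fisher information, the negated closed-form Hessian of ln L."""
    x, removals, r_t, c = _sample_arrays(s)
    r = s.r
    t = p.lam * x**-2.0
    w = np.exp(-t - log1mexp(t))
    i_tt = r / p.theta**2
    cross = np.sum((1.0 + removals) * x**-2.0 * w)
    i_ll = r / p.lam**2 + np.sum(
        (p.theta * (1.0 + removals) - 1.0) * x**-4.0 * w * (1.0 + w)
    )
    if r_t > 0:
        tc = p.lam * c**-2.0
        wc = np.exp(-tc - log1mexp(tc))
        cross += r_t * c**-2.0 * wc
        i_ll += p.theta * r_t * c**-4.0 * wc * (1.0 + wc)
    # Hessian is [[-i_tt, +cross], [+cross, -i_ll]]; information negates it.
    return np.array([[i_tt, -cross], [-cross, i_ll]])


def _invert_info(info: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"observed information is numerically singular (cond={cond:.3g})"
        )
    return np.linalg.inv(info)


def _init_lam(s: PHTICSample) -> float:
    # crude scale proxy: lam such that the median observation sits near the
    # distribution's bulk, lam0 = median(x)^2 * ln 2
    med = float(np.median(s.times_array()))
    return med**2 * np.log(2.0)


def _profile_score_lam(lam: float, s: PHTICSample) -> float:
    th = profile_theta(lam, s)
    return float(score(IERParams(th, lam), s)[1])


def fit_mle(s: PHTICSample, init: IERParams | None = None) -> FitResult:
    """Maximize the PHT-ICS log-likelihood.

    The profiled score in ``lam`` is bracketed on a multiplicative grid around
    the initial value and solved with Brent's method; if no sign change is
    found, a Nelder-Mead search on (ln theta, ln lam) is used instead.
    """
    if s.r < 2:
        raise ValueError("need at least 2 observed failures to fit 2 parameters")
    lam0 = init.lam if init is not None else _init_lam(s)

    bracket = None
    lo = hi = lam0
    g0 = _profile_score_lam(lam0, s)
    for _ in range(60):
        if g0 > 0:
            hi = lo * 2.0
            g1 = _profile_score_lam(hi, s)
            if g1 <= 0:
                bracket = (lo, hi)
                break
            lo, g0 = hi, g1
        else:
            lo = hi / 2.0
            g1 = _profile_score_lam(lo, s)
            if g1 >= 0:
                bracket = (lo, hi)
                break
            hi, g0 = lo, g1

    iterations = 0
    if bracket is not None:
        sol = optimize.root_scalar(
            _profile_score_lam,
            args=(s,),
            bracket=bracket,
            method="brentq",
            xtol=1e-12,
            rtol=1e-14,
        )
        lam_hat = float(sol.root)
        theta_hat = profile_theta(lam_hat, s)
        iterations = int(sol.iterations)
    else:  # pragma: no cover - exercised only on pathological samples
        th0 = init.theta if init is not None else profile_theta(lam0, s)
        res = optimize.minimize(
            lambda lp: -log_likelihood(IERParams(*np.exp(lp)), s),
            np.log([th0, lam0]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 2000},
        )
        theta_hat, lam_hat = np.exp(res.x)
        iterations = int(res.nit)

    p_hat = IERParams(float(theta_hat), float(lam_hat))
    grad = score(p_hat, s)
    converged = bool(np.max(np.abs(grad)) < 1e-6 * max(1.0, s.r))
    cov = _invert_info(observed_info(p_hat, s))
    return FitResult(
        theta_hat=p_hat.theta,
        lam_hat=p_hat.lam,
        loglik=log_likelihood(p_hat, s),
        cov=cov,
        method="MLE",
        converged=converged,
        iterations=iterations,
    )


def aci_normal(estimate: float, se: float, level: float = 0.95) -> ConfidenceInterval:
    """Normal-approximation interval, estimate +/- z_{gamma/2} * se.

    The lower bound may be negative even for positive parameters; it is not
    truncated (use :func:`aci_lognormal` for a positivity-respecting interval).
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return ConfidenceInterval(estimate - z * se, estimate + z * se, level, "ACI_NA")


def aci_lognormal(estimate: float, se: float, level: float = 0.95) -> ConfidenceInterval:
    """Log-transformed normal interval, exp(ln(est) +/- z * se/est); bounds > 0."""
    if estimate <= 0:
        raise ValueError("estimate must be positive for a log-scale interval")
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * se / estimate
    return ConfidenceInterval(
        estimate * np.exp(-half), estimate * np.exp(half), level, "ACI_NL"
    )


def estimate_rh(fit: FitResult, x: float) -> tuple[float, float]:
    """Invariance estimates (R(x), H(x)) at the fitted parameters."""
    p = fit.params
    return float(model.reliability(x, p)), float(model.hazard(x, p))


def rh_gradients(p: IERParams, x: float) -> DeltaGradient:
    """Closed-form gradients of R(x) and H(x) with respect to (theta, lam)."""
    t = p.lam * x**-2.0
    e = np.exp(-t)
    v = -np.expm1(-t)  # 1 - e^{-t}
    logv = log1mexp(t)
    r_val = np.exp(p.theta * logv)
    d_r_dtheta = r_val * logv
    d_r_dlam = p.theta * x**-2.0 * e * np.exp((p.theta - 1.0) * logv)
    d_h_dtheta = 2.0 * p.lam * x**-3.0 * e / v
    d_h_dlam = (
        2.0 * p.theta * x**-3.0 * e * ((1.0 - p.lam * x**-2.0) * v - p.lam * x**-2.0 * e)
    ) / v**2
    return DeltaGradient(
        float(d_r_dtheta), float(d_r_dlam), float(d_h_dtheta), float(d_h_dlam)
    )


def delta_variance(fit: FitResult, x: float) -> tuple[float, float]:
    """Delta-method variances of R(x) and H(x) at the fit."""
    g = rh_gradients(fit.params, x)
    psi_r = np.array([g.dR_dtheta, g.dR_dlam])
    psi_h = np.array([g.dH_dtheta, g.dH_dlam])
    var_r = float(psi_r @ fit.cov @ psi_r)
    var_h = float(psi_h @ fit.cov @ psi_h)
    return max(var_r, 0.0), max(var_h, 0.0)
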