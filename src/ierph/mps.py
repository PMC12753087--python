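"""Maximum-product-of-spacings (MPS) inference under PHT-ICS.

The MPS criterion replaces the likelihood's density factors by cdf increments
between consecutive ordered failures, with the conventions F(x_0) = 0 and
F(x_{r+1}) = 1:

    s(theta, lam) = sum_{i=1}^{r+1} ln[ F(x_i) - F(x_{i-1}) ]
                    + theta * sum_i R_i ln(1 - e^{-lam x_i^-2})
                    + theta * R_T ln(1 - e^{-lam C^-2}),

i.e. removed survivors enter as survival powers exactly as in the likelihood.
MPS estimators are consistent and tend to beat the MLE in small samples; they
share the invariance property, so R(x) and H(x) estimates are plug-ins.

Numerics: with L_i = ln(1 - e^{-lam x_i^-2}) the i-th spacing factors as
exp(theta * L_{i-1}) * m_i where m_i = -expm1(theta * (L_i - L_{i-1})) lies in
(0, 1].  All spacing ratios needed for the gradient and Hessian are computed
with the exp(theta * L) factor cancelled, which avoids the catastrophic
cancellation a naive difference of two nearly-equal cdf values suffers when
lam * x^-2 is large.

Tied observations (which occur in real relief-time data recorded to one
decimal) produce zero spacings; following the usual remedy the zero spacing
is replaced by the density f(x_i), keeping the objective finite.  Gradient
and Hessian handle tied pairs with the matching density derivatives, so
analytic and numeric derivatives agree on any sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .censoring import PHTICSample
from .mle import FitResult, _init_lam, _invert_info, profile_theta
from .model import IERParams, log1mexp

__all__ = [
    "SpacingContext",
    "spacing_context",
    "log_spacing_objective",
    "mps_gradient",
    "mps_observed_info",
    "fit_mps",
]


@dataclass(frozen=True)
class SpacingContext:
    """Augmented cdf values and spacings at a parameter point."""

    cdf_values: np.ndarray  # length r+2, F(x_0)=0 ... F(x_{r+1})=1
    spacings: np.ndarray  # length r+1, consecutive cdf increments
    tie_mask: np.ndarray  # length r+1, True where the spacing is a tie
    censor_obs: np.ndarray  # R_i * ln(1 - e^{-lam x_i^-2})
    censor_terminal: float  # R_T * ln(1 - e^{-lam C^-2})


def _tie_mask(x: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(x) + 1, dtype=bool)
    mask[1:-1] = np.diff(x) == 0.0
    return mask


def _spacing_pieces(p: IERParams, x: np.ndarray):
    """Left/right per-spacing ingredients with the exp(theta*L) factor split off.

    Returns (L_left, m, pieces) where spacing_i = exp(theta * L_left[i]) * m[i]
    and ``pieces`` holds the per-observation arrays (L, G, P, K) needed for
    derivative ratios; boundary conventions give L_left[0] = 0 and m[-1] = 1.
    """
    th, lam = p.theta, p.lam
    t = lam * x**-2.0
    big_l = log1mexp(t)  # ln v_i, negative, decreasing in i
    w = np.exp(-t - big_l)  # e^{-t} / v
    big_g = x**-2.0 * w  # d ln v / d lam
    big_p = big_g * (1.0 + th * big_l)
    big_k = (th - 1.0) * big_g**2 - x**-2.0 * big_g

    left = {
        "L": np.concatenate(([0.0], big_l)),
        "G": np.concatenate(([0.0], big_g)),
        "P": np.concatenate(([0.0], big_p)),
        "K": np.concatenate(([0.0], big_k)),
    }
    right = {
        "L": np.concatenate((big_l, [0.0])),
        "G": np.concatenate((big_g, [0.0])),
        "P": np.concatenate((big_p, [0.0])),
        "K": np.concatenate((big_k, [0.0])),
    }
    m = -np.expm1(th * (right["L"] - left["L"]))
    m[-1] = 1.0  # last spacing: the right endpoint has survival 0
    return left, right, m


def spacing_context(p: IERParams, s: PHTICSample) -> SpacingContext:
    x = s.times_array()
    logv = log1mexp(p.lam * x**-2.0)
    surv = np.concatenate(([1.0], np.exp(p.theta * logv), [0.0]))
    terminal = float(s.R_T) * float(log1mexp(p.lam * s.C**-2.0)) if s.R_T > 0 else 0.0
    return SpacingContext(
        cdf_values=1.0 - surv,
        spacings=surv[:-1] - surv[1:],
        tie_mask=_tie_mask(x),
        censor_obs=s.removals_array() * logv,
        censor_terminal=terminal,
    )


def _tie_arrays(p: IERParams, x: np.ndarray, tie: np.ndarray):
    idx = np.flatnonzero(tie[1:-1]) + 1
    tx = x[idx]
    t = p.lam * tx**-2.0
    logv = log1mexp(t)
    w = np.exp(-t - logv)
    return tx, logv, w


def log_spacing_objective(p: IERParams, s: PHTICSample) -> float:
    x = s.times_array()
    tie = _tie_mask(x)
    left, _, m = _spacing_pieces(p, x)
    keep = ~tie
    with np.errstate(divide="ignore"):
        value = float(np.sum(p.theta * left["L"][keep] + np.log(m[keep])))
    if tie.any():
        tx, logv, _ = _tie_arrays(p, x, tie)
        value += float(
            np.sum(
                np.log(2.0 * p.theta * p.lam)
                - 3.0 * np.log(tx)
                + (p.theta - 1.0) * logv
                - p.lam * tx**-2.0
            )
        )
    ctx_censor = float(np.sum(s.removals_array() * log1mexp(p.lam * x**-2.0)))
    if s.R_T > 0:
        ctx_censor += s.R_T * float(log1mexp(p.lam * s.C**-2.0))
    return value + p.theta * ctx_censor


def _censor_pieces(p: IERParams, s: PHTICSample):
    """Gradient and Hessian pieces of the survival-power censoring terms."""
    x = s.times_array()
    removals = s.removals_array()
    t = p.lam * x**-2.0
    logv = log1mexp(t)
    w = np.exp(-t - logv)
    g_th = float(np.sum(removals * logv))
    g_l_unit = float(np.sum(removals * x**-2.0 * w))
    h_ll_unit = -float(np.sum(removals * x**-4.0 * w * (1.0 + w)))
    if s.R_T > 0:
        c = float(s.C)
        tc = p.lam * c**-2.0
        logvc = float(log1mexp(tc))
        wc = float(np.exp(-tc - logvc))
        g_th += s.R_T * logvc
        g_l_unit += s.R_T * c**-2.0 * wc
        h_ll_unit -= s.R_T * c**-4.0 * wc * (1.0 + wc)
    return g_th, g_l_unit, h_ll_unit


def _spacing_ratios(left, right, m):
    """First/second derivative ratios (d spacing / spacing) per spacing."""

    def ratio(a_left, a_right):
        return (a_left - a_right) + a_right * m

    # tied spacings have m = 0; their entries are discarded by the callers
    with np.errstate(divide="ignore", invalid="ignore"):
        d_th = ratio(left["L"], right["L"]) / m
        d_l = ratio(left["G"], right["G"]) / m
        d_tt = ratio(left["L"] ** 2, right["L"] ** 2) / m
        d_tl = ratio(left["P"], right["P"]) / m
        d_ll = ratio(left["K"], right["K"]) / m
    return d_th, d_l, d_tt, d_tl, d_ll


def mps_gradient(p: IERParams, s: PHTICSample) -> np.ndarray:
    """Analytic gradient of the log-spacing objective, (d/dtheta, d/dlam)."""
    x = s.times_array()
    tie = _tie_mask(x)
    left, right, m = _spacing_pieces(p, x)
    d_th, d_l, *_ = _spacing_ratios(left, right, m)
    keep = ~tie
    g_th = float(np.sum(d_th[keep]))
    g_l = p.theta * float(np.sum(d_l[keep]))
    if tie.any():
        tx, logv, w = _tie_arrays(p, x, tie)
        g_th += float(np.sum(1.0 / p.theta + logv))
        g_l += float(np.sum(1.0 / p.lam - tx**-2.0 + (p.theta - 1.0) * tx**-2.0 * w))
    c_th, c_l_unit, _ = _censor_pieces(p, s)
    return np.array([g_th + c_th, g_l + p.theta * c_l_unit])


def mps_observed_info(p: IERParams, s: PHTICSample) -> np.ndarray:
    """Negated closed-form Hessian of the log-spacing objective."""
    x = s.times_array()
    tie = _tie_mask(x)
    left, right, m = _spacing_pieces(p, x)
    d_th, d_l, d_tt, d_tl, d_ll = _spacing_ratios(left, right, m)
    keep = ~tie
    h_tt = float(np.sum(d_tt[keep] - d_th[keep] ** 2))
    h_tl = float(np.sum(d_tl[keep] - p.theta * d_l[keep] * d_th[keep]))
    h_ll = float(
        p.theta * np.sum(d_ll[keep]) - p.theta**2 * np.sum(d_l[keep] ** 2)
    )
    if tie.any():
        tx, logv, w = _tie_arrays(p, x, tie)
        n_tie = tx.size
        h_tt += -n_tie / p.theta**2
        cross = float(np.sum(tx**-2.0 * w))
        h_tl += cross
        h_ll += -n_tie / p.lam**2 - (p.theta - 1.0) * float(
            np.sum(tx**-4.0 * w * (1.0 + w))
        )
    _, c_l_unit, c_h_ll_unit = _censor_pieces(p, s)
    h_tl += c_l_unit
    h_ll += p.theta * c_h_ll_unit
    return -np.array([[h_tt, h_tl], [h_tl, h_ll]])


def fit_mps(s: PHTICSample, init: IERParams | None = None) -> FitResult:
    """Maximize the log-spacing objective in (ln theta, ln lam).

    L-BFGS-B with the analytic gradient; Nelder-Mead fall-back.  Covariance is
    the inverse of the MPS observed information, used for normal-approximation
    intervals exactly as with the MLE.
    """
    if s.r < 2:
        raise ValueError("need at least 2 observed failures to fit 2 parameters")
    if init is None:
        lam0 = _init_lam(s)
        init = IERParams(profile_theta(lam0, s), lam0)

    def neg(lp):
        lp = np.clip(lp, -40.0, 40.0)
        value = -log_spacing_objective(IERParams(*np.exp(lp)), s)
        return value if np.isfinite(value) else 1e308

    def neg_grad(lp):
        lp = np.clip(lp, -40.0, 40.0)
        th, lam = np.exp(lp)
        g = mps_gradient(IERParams(th, lam), s)
        return -g * np.array([th, lam])  # chain rule to log-parameters

    x0 = np.log([init.theta, init.lam])
    res = optimize.minimize(
        neg, x0, jac=neg_grad, method="L-BFGS-B",
        bounds=[(-40.0, 40.0)] * 2,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    best = res
    alt = None
    if not res.success or not np.all(np.isfinite(res.x)):
        alt = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 4000},
        )
        if alt.fun < best.fun:
            best = alt
    theta_hat, lam_hat = np.exp(np.clip(best.x, -40.0, 40.0))
    p_hat = IERParams(float(theta_hat), float(lam_hat))
    grad = mps_gradient(p_hat, s)
    converged = bool(np.max(np.abs(grad)) < 1e-5 * max(1.0, s.r))
    cov = _invert_info(mps_observed_info(p_hat, s))
    return FitResult(
        theta_hat=p_hat.theta,
        lam_hat=p_hat.lam,
        loglik=log_spacing_objective(p_hat, s),
        cov=cov,
        method="MPS",
        converged=converged,
        iterations=int(best.nit),
    )
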