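"""Bayesian estimation for the IER model under PHT-ICS.

Independent Gamma(a, b) and Gamma(c, d) priors (rate parameterization, prior
means a/b and c/d) on the shape ``theta`` and scale ``lam`` give the joint
posterior kernel

    pi(theta, lam | x) ∝ theta^{a+r-1} lam^{c+r-1}
        * exp(-[theta*b + lam*(d + sum x_i^-2)])
        * (1 - e^{-lam C^-2})^{theta R_T}
        * prod_i (1 - e^{-lam x_i^-2})^{theta(1+R_i) - 1}.

The theta full conditional is exactly Gamma(a + r, b + Q(lam)) with Q the
profiled-likelihood factor; the lam conditional has no closed form.  The
default sampler is Metropolis-Hastings within Gibbs with normal random-walk
proposals (scales taken from the MLE's asymptotic standard deviations,
initialized at the MLE); a Gibbs variant that draws theta exactly from its
Gamma conditional is provided as an independent cross-check.

Point estimates are posterior means (squared-error loss) or LINEX estimates
-(1/a) ln E[e^{-a xi}]; interval estimates are equal-tailed quantile intervals
and highest-posterior-density (shortest sorted-window) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gaussian_kde, skew

from .censoring import PHTICSample
from .mle import FitResult, _q_factor, fit_mle
from .model import IERParams, log1mexp

__all__ = [
    "GammaPriorPair",
    "McmcSettings",
    "LossSpec",
    "PosteriorDraws",
    "PosteriorSummary",
    "log_full_conditional_theta",
    "log_full_conditional_lambda",
    "run_mh_within_gibbs",
    "run_gibbs_theta",
    "bayes_point",
    "equal_tailed_interval",
    "hpd_interval",
    "posterior_summary",
]


@dataclass(frozen=True)
class GammaPriorPair:
    """Hyperparameters (a, b) for theta and (c, d) for lam, rate form."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) <= 0:
            raise ValueError("all gamma hyperparameters must be positive")

    @classmethod
    def noninformative(cls, eps: float = 0.001) -> "GammaPriorPair":
        """Near-flat prior with all hyperparameters equal to ``eps``."""
        return cls(eps, eps, eps, eps)


@dataclass(frozen=True)
class McmcSettings:
    """Chain length, burn-in, proposal scales and seed.

    ``proposal_sd_theta``/``proposal_sd_lambda`` default to None, meaning
    "use the MLE asymptotic standard deviations times ``proposal_factor``".
    """

    n_iter: int = 12_000
    burn_in: int = 2_000
    proposal_sd_theta: float | None = None
    proposal_sd_lambda: float | None = None
    proposal_factor: float = 1.0
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        for sd in (self.proposal_sd_theta, self.proposal_sd_lambda):
            if sd is not None and sd <= 0:
                raise ValueError("proposal scales must be positive")
        if self.proposal_factor <= 0 or self.thin < 1:
            raise ValueError("proposal_factor must be > 0 and thin >= 1")


@dataclass(frozen=True)
class LossSpec:
    """Squared-error ('SE') or LINEX loss with asymmetry parameter ``a``."""

    kind: str = "SE"
    a: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("SE", "LINEX"):
            raise ValueError("loss kind must be 'SE' or 'LINEX'")
        if self.kind == "LINEX" and self.a == 0.0:
            raise ValueError("LINEX requires a != 0 (a -> 0 is the SE limit)")


@dataclass(frozen=True)
class PosteriorDraws:
    theta_chain: np.ndarray
    lambda_chain: np.ndarray
    r_chain: np.ndarray
    h_chain: np.ndarray
    x: float
    acceptance_rate_theta: float
    acceptance_rate_lambda: float
    settings: McmcSettings = field(compare=False)

    def chain(self, name: str) -> np.ndarray:
        return {
            "theta": self.theta_chain,
            "lambda": self.lambda_chain,
            "R": self.r_chain,
            "H": self.h_chain,
        }[name]


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    mode: float
    q1: float
    median: float
    q3: float
    sd: float
    skewness: float


def _loglik_terms(s: PHTICSample):
    x = s.times_array()
    removals = s.removals_array()
    inv_sq = x**-2.0
    return x, removals, inv_sq, float(inv_sq.sum()), float(s.R_T), float(s.C)


def log_full_conditional_theta(
    theta: float, lam: float, s: PHTICSample, prior: GammaPriorPair
) -> float:
    """log pi(theta | lam, x) up to a constant: a Gamma(a+r, b+Q(lam)) kernel."""
    if theta <= 0:
        return -np.inf
    return float((prior.a + s.r - 1.0) * np.log(theta) - theta * (prior.b + _q_factor(lam, s)))


def log_full_conditional_lambda(
    theta: float, lam: float, s: PHTICSample, prior: GammaPriorPair
) -> float:
    """log pi(lam | theta, x) up to a constant."""
    if lam <= 0:
        return -np.inf
    x, removals, inv_sq, sum_inv_sq, r_t, c = _loglik_terms(s)
    logv = log1mexp(lam * inv_sq)
    value = (
        (prior.c + s.r - 1.0) * np.log(lam)
        - lam * (prior.d + sum_inv_sq)
        + np.sum((theta * (1.0 + removals) - 1.0) * logv)
    )
    if r_t > 0:
        value += theta * r_t * log1mexp(lam * c**-2.0)
    return float(value)


def _resolve_proposals(
    s: PHTICSample, settings: McmcSettings, mle: FitResult | None
) -> tuple[float, float, IERParams]:
    need_mle = (
        settings.proposal_sd_theta is None
        or settings.proposal_sd_lambda is None
        or mle is None
    )
    if need_mle and mle is None:
        mle = fit_mle(s)
    init = IERParams(mle.theta_hat, mle.lam_hat)
    sd_th = settings.proposal_sd_theta
    sd_l = settings.proposal_sd_lambda
    if sd_th is None:
        sd_th = mle.se_theta * settings.proposal_factor
    if sd_l is None:
        sd_l = mle.se_lam * settings.proposal_factor
    return float(sd_th), float(sd_l), init


def _run_sampler(
    s: PHTICSample,
    prior: GammaPriorPair,
    settings: McmcSettings,
    x: float,
    mle: FitResult | None,
    gibbs_theta: bool,
) -> PosteriorDraws:
    sd_th, sd_l, init = _resolve_proposals(s, settings, mle)
    rng = np.random.default_rng(settings.seed)
    th, lam = init.theta, init.lam
    n, burn = settings.n_iter, settings.burn_in
    kept = (n - burn + settings.thin - 1) // settings.thin
    th_chain = np.empty(kept)
    lam_chain = np.empty(kept)
    acc_th = acc_l = 0
    lp_th = log_full_conditional_theta(th, lam, s, prior)
    k = 0
    a_post = prior.a + s.r
    for j in range(n):
        if gibbs_theta:
            th = rng.gamma(a_post, 1.0 / (prior.b + _q_factor(lam, s)))
            acc_th += 1
        else:
            prop = th + sd_th * rng.standard_normal()
            lp_prop = log_full_conditional_theta(prop, lam, s, prior)
            if np.log(rng.uniform()) < lp_prop - lp_th:
                th, lp_th, acc_th = prop, lp_prop, acc_th + 1
        lp_l = log_full_conditional_lambda(th, lam, s, prior)
        prop = lam + sd_l * rng.standard_normal()
        lp_prop = log_full_conditional_lambda(th, prop, s, prior)
        if np.log(rng.uniform()) < lp_prop - lp_l:
            lam, acc_l = prop, acc_l + 1
        if not gibbs_theta:
            lp_th = log_full_conditional_theta(th, lam, s, prior)
        if j >= burn and (j - burn) % settings.thin == 0:
            th_chain[k] = th
            lam_chain[k] = lam
            k += 1
    th_chain = th_chain[:k]
    lam_chain = lam_chain[:k]
    t = lam_chain * x**-2.0
    logv = log1mexp(t)
    r_chain = np.exp(th_chain * logv)
    h_chain = 2.0 * th_chain * lam_chain * x**-3.0 * np.exp(-t - logv)
    return PosteriorDraws(
        theta_chain=th_chain,
        lambda_chain=lam_chain,
        r_chain=r_chain,
        h_chain=h_chain,
        x=float(x),
        acceptance_rate_theta=acc_th / n,
        acceptance_rate_lambda=acc_l / n,
        settings=settings,
    )


def run_mh_within_gibbs(
    s: PHTICSample,
    prior: GammaPriorPair,
    settings: McmcSettings,
    x: float = 0.5,
    mle: FitResult | None = None,
) -> PosteriorDraws:
    """Metropolis-Hastings within Gibbs sampler for (theta, lam, R(x), H(x)).

    Normal random-walk proposals centred at the current value; proposals at or
    below zero are rejected outright (the target density is zero there).  The
    chain is initialized at the MLE; the first ``burn_in`` iterations are
    discarded.
    """
    return _run_sampler(s, prior, settings, x, mle, gibbs_theta=False)


def run_gibbs_theta(
    s: PHTICSample,
    prior: GammaPriorPair,
    settings: McmcSettings,
    x: float = 0.5,
    mle: FitResult | None = None,
) -> PosteriorDraws:
    """Cross-check sampler: theta drawn exactly from its Gamma conditional."""
    return _run_sampler(s, prior, settings, x, mle, gibbs_theta=True)


def bayes_point(draws, loss: LossSpec = LossSpec()) -> float:
    """Posterior point estimate under squared-error or LINEX loss."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no posterior draws")
    if loss.kind == "SE":
        return float(draws.mean())
    # LINEX: -(1/a) ln mean(exp(-a * draws)), in log-sum-exp form
    return float(-(logsumexp(-loss.a * draws) - np.log(draws.size)) / loss.a)


def equal_tailed_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """(gamma/2, 1-gamma/2) empirical quantiles (linear interpolation)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    draws = np.asarray(draws, dtype=float)
    lo, hi = np.quantile(draws, [(1 - level) / 2.0, (1 + level) / 2.0])
    return float(lo), float(hi)


def hpd_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing a ``level`` fraction of the sorted draws."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    draws = np.sort(np.asarray(draws, dtype=float))
    m = draws.size
    window = int(np.floor(level * m))
    if window < 1 or window >= m:
        raise ValueError(f"too few draws ({m}) for a {level:.0%} HPD interval")
    widths = draws[window:] - draws[: m - window]
    j = int(np.argmin(widths))
    return float(draws[j]), float(draws[j + window])


def posterior_summary(draws) -> PosteriorSummary:
    """Mean, KDE mode, quartiles, SD (n-1) and moment skewness of a chain."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no posterior draws")
    q1, q2, q3 = np.quantile(draws, [0.25, 0.5, 0.75])
    if np.ptp(draws) == 0.0:
        mode = float(draws[0])
        sd = 0.0
        skw = 0.0
    else:
        kde = gaussian_kde(draws)
        grid = np.linspace(draws.min(), draws.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
        sd = float(draws.std(ddof=1))
        skw = float(skew(draws))
    return PosteriorSummary(
        mean=float(draws.mean()),
        mode=mode,
        q1=float(q1),
        median=float(q2),
        q3=float(q3),
        sd=sd,
        skewness=skw,
    )
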