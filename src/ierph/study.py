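"""Monte-Carlo evaluation harness, goodness of fit and real-data workflow.

Point estimators are compared by their average point estimate (APE), root
mean squared error (RMSE) and mean relative absolute bias (MRAB); interval
estimators by average confidence length (ACL) and coverage percentage (CP).
The harness replays a censoring design many times, fits the MLE, MPS and
(optionally) Bayes estimators in each replicate, and aggregates the metrics
into tidy tables, with Monte-Carlo standard errors alongside so comparisons
at reduced replicate counts remain principled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import kolmogorov

from . import bayes as _bayes
from . import model
from .censoring import (
    CensoringPlan,
    EmptySampleError,
    PHTICSample,
    build_scheme,
    draw_progressive_type2,
    truncate_phtics,
)
from .datasets import censored_sample, relief_times, table_samples
from .mle import aci_lognormal, aci_normal, delta_variance, estimate_rh, fit_mle, log_likelihood
from .model import IERParams
from .mps import fit_mps

__all__ = [
    "metric_ape",
    "metric_rmse",
    "metric_mrab",
    "metric_acl",
    "metric_cp",
    "ks_gof",
    "empirical_reliability",
    "loglik_grid",
    "complete_sample",
    "SimulationDesign",
    "MetricTable",
    "run_monte_carlo",
    "real_data_report",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def metric_ape(estimates) -> float:
    """Average point estimate (the plain mean of the replicate estimates)."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(estimates.mean())


def metric_rmse(estimates, truth: float) -> float:
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def metric_mrab(estimates, truth: float) -> float:
    """Mean of |estimate - truth| / truth."""
    if truth == 0:
        raise ValueError("MRAB undefined for truth = 0")
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.mean(np.abs(estimates - truth)) / abs(truth))


def metric_acl(intervals) -> float:
    """Average width of (lower, upper) interval pairs."""
    arr = np.asarray(intervals, dtype=float)
    if arr.size == 0:
        raise ValueError("no intervals")
    return float(np.mean(arr[:, 1] - arr[:, 0]))


def metric_cp(intervals, truth: float) -> float:
    """Coverage percentage: 100 x fraction of intervals containing the truth."""
    arr = np.asarray(intervals, dtype=float)
    if arr.size == 0:
        raise ValueError("no intervals")
    return float(100.0 * np.mean((arr[:, 0] <= truth) & (truth <= arr[:, 1])))


# ---------------------------------------------------------------------------
# goodness of fit and descriptive tools
# ---------------------------------------------------------------------------


def ks_gof(data, p: IERParams) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against F(.; p).

    Returns (D, p-value).  The p-value uses the asymptotic Kolmogorov
    distribution of sqrt(n) * D with the parameters treated as known (no
    estimated-parameter correction) — the convention that matches plugging
    the fitted parameters straight into the test.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("no data")
    d = float(stats.kstest(data, lambda q: model.cdf(q, p)).statistic)
    return d, float(kolmogorov(np.sqrt(data.size) * d))


class empirical_reliability:
    """Right-continuous step estimate of R(x): the proportion of data > x."""

    def __init__(self, data):
        data = np.sort(np.asarray(data, dtype=float))
        if data.size == 0:
            raise ValueError("no data")
        self._data = data
        self.n = data.size

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return (self.n - np.searchsorted(self._data, x, side="right")) / self.n

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, R(x)) pairs at the observed jump points, for plotting."""
        xs = np.unique(self._data)
        return xs, self(xs)


def complete_sample(data, T: float | None = None) -> PHTICSample:
    """Wrap a complete (uncensored) dataset as a degenerate PHT-ICS sample."""
    data = np.sort(np.asarray(data, dtype=float))
    n = data.size
    if T is None:
        T = float(data[-1]) * 2.0
    plan = CensoringPlan(n=n, m=n, removals=(0,) * n, T=T)
    return truncate_phtics(data, plan)


def loglik_grid(
    s: PHTICSample, theta_range, lam_range, resolution: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense log-likelihood surface for contour plots.

    Returns (theta_grid, lam_grid, matrix) with matrix[i, j] the log-likelihood
    at (theta_grid[i], lam_grid[j]).
    """
    th_grid = np.linspace(*theta_range, resolution)
    lam_grid = np.linspace(*lam_range, resolution)
    out = np.empty((resolution, resolution))
    for i, th in enumerate(th_grid):
        for j, lam in enumerate(lam_grid):
            out[i, j] = log_likelihood(IERParams(th, lam), s)
    return th_grid, lam_grid, out


# ---------------------------------------------------------------------------
# Monte-Carlo study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationDesign:
    """Configuration of a Monte-Carlo study over censoring scenarios."""

    true_params: IERParams = IERParams(0.4, 0.8)
    T_values: tuple[float, ...] = (1.5, 2.5)
    nm_pairs: tuple[tuple[int, int], ...] = ((40, 20), (40, 32), (80, 40), (80, 64))
    schemes: tuple[str, ...] = ("scheme1", "scheme2", "scheme3")
    reps: int = 1000
    priors: tuple[_bayes.GammaPriorPair, ...] = ()
    linex_a: tuple[float, ...] = (-2.0, 2.0)
    mcmc: _bayes.McmcSettings = _bayes.McmcSettings(n_iter=12_000, burn_in=2_000)
    level: float = 0.95
    mission_time: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.mission_time > 0:
            raise ValueError("mission_time must be positive")


@dataclass
class MetricTable:
    """Aggregated study output: tidy point and interval metric tables."""

    points: pd.DataFrame
    intervals: pd.DataFrame
    redraws: int = 0
    fit_failures: int = 0

    def to_csv(self, points_path, intervals_path) -> None:
        self.points.to_csv(points_path, index=False)
        self.intervals.to_csv(intervals_path, index=False)


_ESTIMANDS = ("theta", "lambda", "R", "H")


def _true_values(design: SimulationDesign) -> dict[str, float]:
    p, t0 = design.true_params, design.mission_time
    return {
        "theta": p.theta,
        "lambda": p.lam,
        "R": float(model.reliability(t0, p)),
        "H": float(model.hazard(t0, p)),
    }


def _point_and_intervals(fit, x0: float, level: float):
    """Per-replicate estimates and ACI-NA intervals for all four estimands."""
    r_hat, h_hat = estimate_rh(fit, x0)
    var_r, var_h = delta_variance(fit, x0)
    ests = {"theta": fit.theta_hat, "lambda": fit.lam_hat, "R": r_hat, "H": h_hat}
    ses = {
        "theta": fit.se_theta,
        "lambda": fit.se_lam,
        "R": np.sqrt(var_r),
        "H": np.sqrt(var_h),
    }
    cis = {
        key: (lambda ci: (ci.lower, ci.upper))(aci_normal(ests[key], ses[key], level))
        for key in _ESTIMANDS
    }
    return ests, cis


def run_monte_carlo(design: SimulationDesign) -> MetricTable:
    """Replay every (T, (n, m), scheme) cell of the design.

    Each replicate generates a PHT-ICS sample (replicates with zero observed
    failures are redrawn and counted), fits MLE and MPS with ACI-NA intervals,
    and, when priors are configured, Bayes point estimates (SE and each LINEX
    ``a``) with HPD intervals.  Replicates whose fit fails are skipped and
    counted.  All randomness flows from ``design.seed``.
    """
    truths = _true_values(design)
    x0, level = design.mission_time, design.level
    point_rows: list[dict] = []
    interval_rows: list[dict] = []
    redraws = failures = 0

    cells = [
        (T, n, m, scheme)
        for T in design.T_values
        for n, m in design.nm_pairs
        for scheme in design.schemes
    ]
    for cell_index, (T, n, m, scheme) in enumerate(cells):
        plan = CensoringPlan(n, m, build_scheme(scheme, n, m), T)
        cell_seed = np.random.SeedSequence(
            entropy=design.seed, spawn_key=(cell_index,)
        )
        rng = np.random.default_rng(cell_seed)
        ests: dict[tuple[str, str], list[float]] = {}
        ints: dict[tuple[str, str], list[tuple[float, float]]] = {}

        def push(estimator, values, key=ests):
            for name, v in values.items():
                key.setdefault((name, estimator), []).append(v)

        done = 0
        while done < design.reps:
            try:
                sample = truncate_phtics(
                    draw_progressive_type2(plan, design.true_params, rng),
                    plan,
                )
            except EmptySampleError:
                redraws += 1
                continue
            try:
                mle = fit_mle(sample)
                mps = fit_mps(sample)
            except Exception:
                failures += 1
                done += 1
                continue
            e, ci = _point_and_intervals(mle, x0, level)
            push("MLE", e)
            push("ACI-NA (MLE)", ci, ints)
            e, ci = _point_and_intervals(mps, x0, level)
            push("MPS", e)
            push("ACI-NA (MPS)", ci, ints)
            for k, prior in enumerate(design.priors):
                mh_seed = int(rng.integers(2**31))
                settings = _bayes.McmcSettings(
                    n_iter=design.mcmc.n_iter,
                    burn_in=design.mcmc.burn_in,
                    proposal_factor=design.mcmc.proposal_factor,
                    seed=mh_seed,
                )
                draws = _bayes.run_mh_within_gibbs(
                    sample, prior, settings, x=x0, mle=mle
                )
                label = f"prior{k + 1}"
                chains = {
                    name: draws.chain(cn)
                    for name, cn in zip(_ESTIMANDS, ("theta", "lambda", "R", "H"))
                }
                push(
                    f"SE ({label})",
                    {nm: _bayes.bayes_point(chain) for nm, chain in chains.items()},
                )
                for a in design.linex_a:
                    loss = _bayes.LossSpec("LINEX", a)
                    push(
                        f"LINEX{a:+g} ({label})",
                        {
                            nm: _bayes.bayes_point(chain, loss)
                            for nm, chain in chains.items()
                        },
                    )
                push(
                    f"HPD ({label})",
                    {
                        nm: _bayes.hpd_interval(chain, level)
                        for nm, chain in chains.items()
                    },
                    ints,
                )
            done += 1

        base = {"T": T, "n": n, "m": m, "scheme": scheme}
        for (name, estimator), values in ests.items():
            values = np.asarray(values)
            point_rows.append(
                base
                | {
                    "estimand": name,
                    "estimator": estimator,
                    "reps": values.size,
                    "APE": metric_ape(values),
                    "RMSE": metric_rmse(values, truths[name]),
                    "MRAB": metric_mrab(values, truths[name]),
                    "APE_mcse": float(values.std(ddof=1) / np.sqrt(values.size))
                    if values.size > 1
                    else np.nan,
                }
            )
        for (name, method), pairs in ints.items():
            interval_rows.append(
                base
                | {
                    "estimand": name,
                    "method": method,
                    "reps": len(pairs),
                    "ACL": metric_acl(pairs),
                    "CP": metric_cp(pairs, truths[name]),
                }
            )

    return MetricTable(
        points=pd.DataFrame(point_rows),
        intervals=pd.DataFrame(interval_rows),
        redraws=redraws,
        fit_failures=failures,
    )


# ---------------------------------------------------------------------------
# real-data workflow
# ---------------------------------------------------------------------------


def real_data_report(
    x0: float = 5.0,
    level: float = 0.95,
    linex_a: tuple[float, ...] = (-3.0, -0.03, 3.0),
    mcmc: _bayes.McmcSettings = _bayes.McmcSettings(n_iter=50_000, burn_in=10_000),
    prior: _bayes.GammaPriorPair | None = None,
    seed: int = 0,
    samples: tuple[str, ...] | None = None,
    keep_draws: bool = False,
) -> dict:
    """Full analysis of the bundled arthritis data.

    Complete-data MLE with a K-S fit check, then for each censored sample:
    MLE with SEs and ACI-NA/NL intervals, Bayes (near-noninformative gamma
    priors, M-H within Gibbs) point estimates under SE and LINEX losses,
    equal-tailed (BCI) and HPD intervals, and posterior summary statistics.

    Estimands are labelled by the Eq-style parameterization: ``theta`` is the
    shape exponent and ``lambda`` the scale inside the exponential.
    """
    if prior is None:
        prior = _bayes.GammaPriorPair.noninformative()
    data = relief_times()
    full = complete_sample(data)
    full_fit = fit_mle(full)
    ks_stat, ks_p = ks_gof(data, full_fit.params)

    est_rows: list[dict] = []
    int_rows: list[dict] = []
    sum_rows: list[dict] = []
    all_draws: dict[str, _bayes.PosteriorDraws] = {}
    for idx, name in enumerate(samples if samples is not None else table_samples()):
        s = censored_sample(name)
        fit = fit_mle(s)
        r_hat, h_hat = estimate_rh(fit, x0)
        var_r, var_h = delta_variance(fit, x0)
        settings = _bayes.McmcSettings(
            n_iter=mcmc.n_iter,
            burn_in=mcmc.burn_in,
            proposal_factor=mcmc.proposal_factor,
            seed=seed + idx,
        )
        draws = _bayes.run_mh_within_gibbs(s, prior, settings, x=x0, mle=fit)
        if keep_draws:
            all_draws[name] = draws
        ml_est = {"theta": fit.theta_hat, "lambda": fit.lam_hat, "R": r_hat, "H": h_hat}
        ml_se = {
            "theta": fit.se_theta,
            "lambda": fit.se_lam,
            "R": float(np.sqrt(var_r)),
            "H": float(np.sqrt(var_h)),
        }
        chains = {
            "theta": draws.theta_chain,
            "lambda": draws.lambda_chain,
            "R": draws.r_chain,
            "H": draws.h_chain,
        }
        for par, chain in chains.items():
            summary = _bayes.posterior_summary(chain)
            row = {
                "sample": name,
                "estimand": par,
                "MLE": ml_est[par],
                "MLE_se": ml_se[par],
                "Bayes_SE": summary.mean,
                "Bayes_sd": summary.sd,
            }
            for a in linex_a:
                row[f"LINEX{a:+g}"] = _bayes.bayes_point(chain, _bayes.LossSpec("LINEX", a))
            est_rows.append(row)

            na = aci_normal(ml_est[par], ml_se[par], level)
            nl = aci_lognormal(ml_est[par], ml_se[par], level) if ml_est[par] > 0 else None
            bci = _bayes.equal_tailed_interval(chain, level)
            hpd = _bayes.hpd_interval(chain, level)
            for flavor, lo, hi in [
                ("ACI-NA", na.lower, na.upper),
                ("ACI-NL", *(nl.lower, nl.upper)) if nl else ("ACI-NL", np.nan, np.nan),
                ("BCI", *bci),
                ("HPD", *hpd),
            ]:
                int_rows.append(
                    {
                        "sample": name,
                        "estimand": par,
                        "interval": flavor,
                        "lower": lo,
                        "upper": hi,
                        "length": hi - lo,
                    }
                )
            sum_rows.append(
                {"sample": name, "estimand": par}
                | {
                    "mean": summary.mean,
                    "mode": summary.mode,
                    "Q1": summary.q1,
                    "Q2": summary.median,
                    "Q3": summary.q3,
                    "SD": summary.sd,
                    "skewness": summary.skewness,
                }
            )

    report = {
        "complete_fit": full_fit,
        "ks": {"statistic": ks_stat, "p_value": ks_p},
        "estimates": pd.DataFrame(est_rows),
        "intervals": pd.DataFrame(int_rows),
        "mcmc_summary": pd.DataFrame(sum_rows),
    }
    if keep_draws:
        report["draws"] = all_draws
    return report
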