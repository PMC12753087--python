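"""Posterior machinery: conjugacy, sampler cross-checks, losses, intervals."""

import numpy as np
import pytest
from scipy import stats

import ierph
from ierph.bayes import (
    GammaPriorPair,
    LossSpec,
    McmcSettings,
    bayes_point,
    equal_tailed_interval,
    hpd_interval,
    log_full_conditional_lambda,
    log_full_conditional_theta,
    posterior_summary,
    run_gibbs_theta,
    run_mh_within_gibbs,
)
from ierph.mle import _q_factor

RNG = np.random.default_rng(99)
PRIOR = GammaPriorPair(2.0, 5.0, 4.0, 5.0)


def log_joint(th, lam, s, prior):
    """Log posterior kernel assembled independently from likelihood + prior."""
    return (
        ierph.log_likelihood(ierph.IERParams(th, lam), s)
        + (prior.a - 1) * np.log(th)
        - prior.b * th
        + (prior.c - 1) * np.log(lam)
        - prior.d * lam
    )


def test_theta_conditional_is_joint_minus_lambda_terms(s1):
    lam = 30.0
    offsets = [
        log_joint(th, lam, s1, PRIOR) - log_full_conditional_theta(th, lam, s1, PRIOR)
        for th in np.exp(RNG.uniform(-1, 1, 20))
    ]
    assert np.ptp(offsets) < 1e-8, "difference must be constant in theta"


def test_lambda_conditional_is_joint_minus_theta_terms(s1):
    th = 1.3
    offsets = [
        log_joint(th, lam, s1, PRIOR) - log_full_conditional_lambda(th, lam, s1, PRIOR)
        for lam in np.exp(RNG.uniform(2, 5, 20))
    ]
    assert np.ptp(offsets) < 1e-8, "difference must be constant in lambda"


def test_theta_conditional_is_gamma_kernel(s1):
    """pi(theta | lam) is exactly Gamma(a + r, b + Q(lam))."""
    lam = 40.0
    shape = PRIOR.a + s1.r
    rate = PRIOR.b + _q_factor(lam, s1)
    ths = np.exp(RNG.uniform(-1.5, 1.5, 30))
    ours = np.array([log_full_conditional_theta(t, lam, s1, PRIOR) for t in ths])
    ref = stats.gamma.logpdf(ths, a=shape, scale=1.0 / rate)
    assert np.ptp(ours - ref) < 1e-9
    # analytic mode of the kernel
    grid = np.linspace(0.01, 20, 20000)
    vals = [log_full_conditional_theta(t, lam, s1, PRIOR) for t in grid]
    assert grid[int(np.argmax(vals))] == pytest.approx((shape - 1) / rate, abs=2e-3)


def test_lambda_conditional_reduction_to_gamma(sim_params):
    """With no removals and theta = 1 the lam conditional is Gamma(c+r, d+sum x^-2)."""
    data = ierph.sample_iid(15, sim_params, seed=3)
    s = ierph.complete_sample(data)
    rate = PRIOR.d + float(np.sum(data**-2.0))
    lams = np.exp(RNG.uniform(-2, 1, 30))
    ours = np.array([log_full_conditional_lambda(1.0, l, s, PRIOR) for l in lams])
    ref = stats.gamma.logpdf(lams, a=PRIOR.c + s.r, scale=1.0 / rate)
    assert np.ptp(ours - ref) < 1e-9


def test_lambda_conditional_finite_over_wide_range(s1):
    for lam in np.geomspace(1e-6, 1e3, 40):
        assert np.isfinite(log_full_conditional_lambda(1.3, lam, s1, PRIOR))


def _mcse(chain, batches=25):
    means = chain[: chain.size - chain.size % batches].reshape(batches, -1).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(batches)


def test_mh_agrees_with_conjugate_gibbs_oracle(s1):
    """Primary correctness gate: M-H marginals match exact-Gamma Gibbs."""
    prior = GammaPriorPair.noninformative()
    mle = ierph.fit_mle(s1)
    mh = run_mh_within_gibbs(
        s1, prior, McmcSettings(n_iter=14000, burn_in=3000, seed=21), x=5.0, mle=mle
    )
    gibbs = run_gibbs_theta(
        s1, prior, McmcSettings(n_iter=14000, burn_in=3000, seed=22), x=5.0, mle=mle
    )
    assert gibbs.acceptance_rate_theta == 1.0
    for name in ("theta", "lambda", "R", "H"):
        a, b = mh.chain(name), gibbs.chain(name)
        tol = 3.0 * np.hypot(_mcse(a), _mcse(b))
        assert abs(a.mean() - b.mean()) < tol, name


def test_chains_deterministic_and_positive(s1):
    prior = GammaPriorPair.noninformative()
    mle = ierph.fit_mle(s1)
    settings = McmcSettings(n_iter=3000, burn_in=500, seed=5)
    a = run_mh_within_gibbs(s1, prior, settings, x=5.0, mle=mle)
    b = run_mh_within_gibbs(s1, prior, settings, x=5.0, mle=mle)
    np.testing.assert_array_equal(a.theta_chain, b.theta_chain)
    np.testing.assert_array_equal(a.lambda_chain, b.lambda_chain)
    assert np.all(a.theta_chain > 0) and np.all(a.lambda_chain > 0)
    assert a.theta_chain.size == 2500
    assert 0 < a.acceptance_rate_theta < 1


def test_posterior_tracks_mle_with_flat_prior_and_big_sample(sim_params):
    data = ierph.sample_iid(2000, sim_params, seed=17)
    s = ierph.complete_sample(data)
    mle = ierph.fit_mle(s)
    draws = run_mh_within_gibbs(
        s,
        GammaPriorPair.noninformative(),
        McmcSettings(n_iter=6000, burn_in=1000, seed=2),
        x=0.5,
        mle=mle,
    )
    assert draws.theta_chain.mean() == pytest.approx(mle.theta_hat, rel=0.02)
    assert draws.lambda_chain.mean() == pytest.approx(mle.lam_hat, rel=0.02)


def test_bayes_point_losses():
    draws = RNG.gamma(5.0, 2.0, size=20000)
    se = bayes_point(draws)
    assert se == pytest.approx(draws.mean(), rel=1e-12)
    # LINEX -> SE as a -> 0
    assert bayes_point(draws, LossSpec("LINEX", 1e-8)) == pytest.approx(se, abs=1e-5)
    # Jensen ordering: LINEX(a>0) <= SE <= LINEX(a<0)
    assert bayes_point(draws, LossSpec("LINEX", 2.0)) <= se
    assert se <= bayes_point(draws, LossSpec("LINEX", -2.0))
    const = np.full(100, 3.25)
    for spec in (LossSpec(), LossSpec("LINEX", 2.0), LossSpec("LINEX", -2.0)):
        assert bayes_point(const, spec) == pytest.approx(3.25, rel=1e-12)
    with pytest.raises(ValueError):
        LossSpec("LINEX", 0.0)
    with pytest.raises(ValueError):
        bayes_point(np.array([]), LossSpec())


def test_equal_tailed_interval():
    draws = np.arange(1.0, 101.0)
    lo, hi = equal_tailed_interval(draws, 0.95)
    assert lo == pytest.approx(np.quantile(draws, 0.025))
    assert hi == pytest.approx(np.quantile(draws, 0.975))
    assert lo <= np.median(draws) <= hi
    with pytest.raises(ValueError):
        equal_tailed_interval(draws, 1.2)


def brute_force_hpd(draws, level):
    draws = np.sort(draws)
    window = int(np.floor(level * draws.size))
    best = None
    for j in range(draws.size - window):
        width = draws[j + window] - draws[j]
        if best is None or width < best[0]:
            best = (width, draws[j], draws[j + window])
    return best[1], best[2]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hpd_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    draws = rng.gamma(2.0, 3.0, size=1500)
    assert hpd_interval(draws, 0.95) == brute_force_hpd(draws, 0.95)
    assert hpd_interval(draws, 0.5) == brute_force_hpd(draws, 0.5)


def test_hpd_shorter_than_equal_tailed_and_symmetric_case():
    draws = RNG.standard_normal(60000)
    lo_h, hi_h = hpd_interval(draws, 0.95)
    lo_e, hi_e = equal_tailed_interval(draws, 0.95)
    assert (hi_h - lo_h) <= (hi_e - lo_e)
    # symmetric unimodal sample: the two intervals nearly coincide
    assert (hi_e - lo_e) - (hi_h - lo_h) < 0.02 * (hi_e - lo_e)
    with pytest.raises(ValueError):
        hpd_interval(np.array([1.0, 2.0]), 0.1)


def test_posterior_summary_shapes():
    sym = RNG.standard_normal(100_000)
    summary = posterior_summary(sym)
    assert abs(summary.skewness) < 0.05
    assert summary.q1 <= summary.median <= summary.q3
    assert summary.sd == pytest.approx(1.0, abs=0.02)
    assert abs(summary.mode) < 0.1

    const = posterior_summary(np.full(50, 7.0))
    assert const.sd == 0.0 and const.mean == const.mode == const.median == 7.0
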