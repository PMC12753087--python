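"""Study harness: metric formulas, goodness of fit, Monte-Carlo aggregation."""

import numpy as np
import pytest

import ierph
from ierph.bayes import GammaPriorPair, McmcSettings
from ierph.study import (
    SimulationDesign,
    empirical_reliability,
    ks_gof,
    loglik_grid,
    metric_acl,
    metric_ape,
    metric_cp,
    metric_mrab,
    metric_rmse,
    run_monte_carlo,
)


def test_metric_hand_values():
    assert metric_ape([0.3, 0.5]) == pytest.approx(0.4)
    assert metric_rmse([0.3, 0.5], 0.4) == pytest.approx(0.1)
    assert metric_mrab([0.3, 0.5], 0.4) == pytest.approx(0.25)
    # perfect estimation
    assert metric_rmse([0.4] * 5, 0.4) == 0.0
    assert metric_mrab([0.4] * 5, 0.4) == 0.0
    assert metric_ape([0.4] * 5) == pytest.approx(0.4)
    # RMSE dominates absolute bias
    ests = [0.1, 0.9, 0.4]
    assert metric_rmse(ests, 0.4) >= abs(metric_ape(ests) - 0.4)
    with pytest.raises(ValueError):
        metric_mrab([1.0], 0.0)


def test_interval_metrics():
    truth = 2.0
    pairs = [(1.0, 3.0), (1.5, 3.5), (2.5, 3.0)]
    assert metric_acl(pairs) == pytest.approx(np.mean([2.0, 2.0, 0.5]))
    assert metric_cp(pairs, truth) == pytest.approx(100 * 2 / 3)
    assert metric_cp([(truth - 1, truth + 1)] * 4, truth) == 100.0
    assert metric_acl([(truth - 1, truth + 1)] * 4) == pytest.approx(2.0)
    assert metric_cp([(5.0, 6.0)] * 3, truth) == 0.0


def test_ks_statistic_matches_enumeration(sim_params):
    rng = np.random.default_rng(3)
    data = np.sort(rng.uniform(0.3, 3.0, size=37))
    stat, _ = ks_gof(data, sim_params)
    cdf_vals = ierph.cdf(data, sim_params)
    n = data.size
    brute = max(
        max(abs((i + 1) / n - f), abs(i / n - f)) for i, f in enumerate(cdf_vals)
    )
    assert stat == pytest.approx(brute, abs=1e-12)


def test_ks_converges_for_model_data(sim_params):
    data = ierph.sample_iid(100_000, sim_params, seed=12)
    stat, p = ks_gof(data, sim_params)
    assert stat < 0.01
    assert 0 <= p <= 1


def test_empirical_reliability_steps(relief):
    emp = empirical_reliability(relief)
    assert emp(1.0) == 1.0
    assert emp(100.0) == 0.0
    assert emp(5.0) == pytest.approx(34 / 50)
    data = np.array([1.0, 2.0, 3.0, 4.0])
    emp2 = empirical_reliability(data)
    for k, x in enumerate(data, start=1):
        assert emp2(x) == pytest.approx((4 - k) / 4)
    xs, vals = emp2.as_arrays()
    np.testing.assert_array_equal(xs, data)


def test_loglik_grid_brackets_mle(complete_relief):
    fit = ierph.fit_mle(complete_relief)
    th_grid, lam_grid, surface = loglik_grid(
        complete_relief,
        (fit.theta_hat * 0.7, fit.theta_hat * 1.3),
        (fit.lam_hat * 0.7, fit.lam_hat * 1.3),
        resolution=41,
    )
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    d_th = th_grid[1] - th_grid[0]
    d_lam = lam_grid[1] - lam_grid[0]
    assert abs(th_grid[i] - fit.theta_hat) <= d_th
    assert abs(lam_grid[j] - fit.lam_hat) <= d_lam
    assert surface.max() <= fit.loglik + 1e-9


def test_single_replicate_aggregation_identity(sim_params):
    design = SimulationDesign(
        true_params=sim_params,
        T_values=(1.5,),
        nm_pairs=((40, 20),),
        schemes=("scheme1",),
        reps=1,
        seed=123,
    )
    table = run_monte_carlo(design)
    row = table.points.query("estimand == 'theta' and estimator == 'MLE'").iloc[0]
    assert row["RMSE"] == pytest.approx(abs(row["APE"] - sim_params.theta))
    assert row["MRAB"] == pytest.approx(
        abs(row["APE"] - sim_params.theta) / sim_params.theta
    )
    assert set(table.points["estimator"]) == {"MLE", "MPS"}
    assert table.fit_failures == 0


def test_rmse_improves_with_more_failures(sim_params):
    """Raising m from 20 to 32 at n = 40 must reduce the Monte-Carlo RMSE."""
    common = dict(
        true_params=sim_params,
        T_values=(1.5,),
        schemes=("scheme1",),
        reps=150,
        seed=7,
    )
    small = run_monte_carlo(SimulationDesign(nm_pairs=((40, 20),), **common))
    large = run_monte_carlo(SimulationDesign(nm_pairs=((40, 32),), **common))

    def rmse(tbl, estimator):
        return tbl.points.query(
            "estimand == 'theta' and estimator == @estimator"
        ).iloc[0]["RMSE"]

    assert rmse(large, "MLE") < rmse(small, "MLE")
    assert rmse(large, "MPS") < rmse(small, "MPS")


def test_aci_coverage_near_nominal(sim_params):
    """95% ACI-NA coverage for theta at the (80, 64), T = 2.5, scheme-1 cell."""
    design = SimulationDesign(
        true_params=sim_params,
        T_values=(2.5,),
        nm_pairs=((80, 64),),
        schemes=("scheme1",),
        reps=500,
        seed=42,
    )
    table = run_monte_carlo(design)
    cp = table.intervals.query(
        "estimand == 'theta' and method == 'ACI-NA (MLE)'"
    ).iloc[0]["CP"]
    assert cp == pytest.approx(95.2, abs=2.5)


def test_monte_carlo_with_bayes_column(sim_params):
    design = SimulationDesign(
        true_params=sim_params,
        T_values=(1.5,),
        nm_pairs=((40, 20),),
        schemes=("scheme1",),
        reps=3,
        priors=(GammaPriorPair(2, 5, 4, 5),),
        linex_a=(-2.0, 2.0),
        mcmc=McmcSettings(n_iter=1500, burn_in=300),
        seed=11,
    )
    table = run_monte_carlo(design)
    estimators = set(table.points["estimator"])
    assert {"MLE", "MPS", "SE (prior1)", "LINEX-2 (prior1)", "LINEX+2 (prior1)"} <= estimators
    methods = set(table.intervals["method"])
    assert {"ACI-NA (MLE)", "ACI-NA (MPS)", "HPD (prior1)"} <= methods
    hpd_rows = table.intervals.query("method == 'HPD (prior1)'")
    assert (hpd_rows["ACL"] >= 0).all()
    assert hpd_rows["CP"].between(0, 100).all()


def test_real_data_report_deterministic():
    kwargs = dict(
        mcmc=McmcSettings(n_iter=2500, burn_in=500),
        seed=19,
        samples=("S1",),
    )
    a = ierph.real_data_report(**kwargs)
    b = ierph.real_data_report(**kwargs)
    for key in ("estimates", "intervals", "mcmc_summary"):
        assert a[key].equals(b[key]), key
    est = a["estimates"].set_index("estimand")
    assert est.loc["theta", "MLE"] == pytest.approx(1.30981, abs=1e-4)
    assert est.loc["lambda", "MLE"] == pytest.approx(46.5674, abs=1e-3)
    assert est.loc["R", "MLE"] == pytest.approx(0.8017, abs=1e-3)
    assert est.loc["H", "MLE"] == pytest.approx(0.1794, abs=1e-3)
    assert a["ks"]["statistic"] == pytest.approx(0.1269, abs=1e-3)
    intervals = a["intervals"]
    nl = intervals.query("estimand == 'lambda' and interval == 'ACI-NL'").iloc[0]
    assert nl["lower"] > 0
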