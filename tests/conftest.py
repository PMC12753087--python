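from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ierph

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_params() -> ierph.IERParams:
    """The simulation study's true parameter pair."""
    return ierph.IERParams(0.4, 0.8)


@pytest.fixture(scope="session")
def s1() -> ierph.PHTICSample:
    return ierph.censored_sample("S1")


@pytest.fixture(scope="session")
def relief() -> np.ndarray:
    return ierph.relief_times()


@pytest.fixture(scope="session")
def complete_relief(relief) -> ierph.PHTICSample:
    return ierph.complete_sample(relief)


@pytest.fixture(scope="session")
def tie_free_sample(sim_params) -> ierph.PHTICSample:
    """A censored sample without tied failure times, for derivative oracles."""
    plan = ierph.CensoringPlan(40, 20, ierph.build_scheme("scheme1", 40, 20), 1.5)
    return ierph.generate_phtics(plan, sim_params, seed=11)


def fd_gradient(fun, point, rel_step=1e-6):
    """Central-difference gradient with relative steps."""
    point = np.asarray(point, dtype=float)
    grad = np.empty_like(point)
    for i in range(point.size):
        h = rel_step * max(abs(point[i]), 1.0)
        up, down = point.copy(), point.copy()
        up[i] += h
        down[i] -= h
        grad[i] = (fun(up) - fun(down)) / (2 * h)
    return grad


def fd_hessian(fun, point, rel_step=1e-4):
    """Central-difference Hessian with relative steps."""
    point = np.asarray(point, dtype=float)
    k = point.size
    hess = np.empty((k, k))
    steps = [rel_step * max(abs(v), 1.0) for v in point]
    for i in range(k):
        for j in range(k):
            pp = point.copy(); pp[i] += steps[i]; pp[j] += steps[j]
            pm = point.copy(); pm[i] += steps[i]; pm[j] -= steps[j]
            mp = point.copy(); mp[i] -= steps[i]; mp[j] += steps[j]
            mm = point.copy(); mm[i] -= steps[i]; mm[j] -= steps[j]
            hess[i, j] = (fun(pp) - fun(pm) - fun(mp) + fun(mm)) / (
                4 * steps[i] * steps[j]
            )
    return hess
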