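"""Progressive hybrid Type-I censored sampling (PHT-ICS).

A life test starts with ``n`` units and a progressive censoring plan
``(R_1, ..., R_m)``: at the i-th observed failure, ``R_i`` surviving units are
withdrawn.  The hybrid Type-I variant additionally fixes a threshold time
``T`` and stops at ``min(X_m, T)``:

* Case I  — the m-th failure occurs first; all ``m`` failures are observed and
  the termination point is ``C = X_m``.
* Case II — the clock runs out first; only ``d < m`` failures are observed,
  ``C = T`` and the remaining ``R_T = n - d - sum(R_1..R_d)`` units are removed
  unfailed at ``T``.

This module generates such samples from the IER model (the synthetic-data
engine for the whole package) and round-trips them through a small plain-text
format.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .model import IERParams, quantile

__all__ = [
    "Case",
    "CensoringPlan",
    "PHTICSample",
    "EmptySampleError",
    "build_scheme",
    "draw_progressive_type2",
    "truncate_phtics",
    "assemble_sample",
    "generate_phtics",
    "read_sample",
    "write_sample",
]


class Case(enum.Enum):
    """Which stopping rule fired: the m-th failure (I) or the clock (II)."""

    I = "case1"
    II = "case2"


class EmptySampleError(ValueError):
    """No failure occurred before the threshold time; inference is undefined."""


@dataclass(frozen=True)
class CensoringPlan:
    """Design of a PHT-ICS experiment: (n, m, R_1..R_m, T)."""

    n: int
    m: int
    removals: tuple[int, ...]
    T: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "removals", tuple(int(r) for r in self.removals))
        if self.m < 1 or self.n < self.m:
            raise ValueError(f"need 1 <= m <= n, got n={self.n}, m={self.m}")
        if len(self.removals) != self.m:
            raise ValueError("removals must have length m")
        if any(r < 0 for r in self.removals):
            raise ValueError("removals must be non-negative")
        if sum(self.removals) != self.n - self.m:
            raise ValueError(
                f"removals must sum to n - m = {self.n - self.m}, "
                f"got {sum(self.removals)}"
            )
        if not (self.T > 0):
            raise ValueError("threshold time T must be positive")


@dataclass(frozen=True)
class PHTICSample:
    """A realized PHT-ICS dataset.

    ``times`` are the ``r`` observed (ordered) failure times,
    ``removals_applied`` the per-failure removals actually made, ``C`` the
    termination point, and ``R_T`` the terminal removal (0 in Case I).
    """

    times: tuple[float, ...]
    plan: CensoringPlan
    case: Case
    C: float
    removals_applied: tuple[int, ...]
    R_T: int
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "removals_applied", tuple(int(r) for r in self.removals_applied)
        )
        t = np.asarray(self.times)
        if t.size == 0:
            raise EmptySampleError("sample contains no observed failures")
        if np.any(t <= 0) or np.any(np.diff(t) < 0):
            raise ValueError("failure times must be positive and sorted ascending")
        if len(self.removals_applied) != self.r:
            raise ValueError("removals_applied must have one entry per failure")
        if self.r + sum(self.removals_applied) + self.R_T != self.plan.n:
            raise ValueError(
                "unit accounting violated: n != r + sum(removals) + R_T"
            )
        if self.case is Case.I and (self.r != self.plan.m or self.R_T != 0):
            raise ValueError("Case I requires r = m and R_T = 0")
        if self.case is Case.II and self.r >= self.plan.m:
            raise ValueError("Case II requires r < m")

    @property
    def r(self) -> int:
        return len(self.times)

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def removals_array(self) -> np.ndarray:
        return np.asarray(self.removals_applied, dtype=float)


_SCHEME_KINDS = ("scheme1", "scheme2", "scheme3")


def build_scheme(kind: str, n: int, m: int) -> tuple[int, ...]:
    """The three one-point removal patterns used in the simulation study.

    scheme1 removes all ``n - m`` spares at the first failure, scheme2 at the
    middle failure (index ``ceil(m/2)``), scheme3 at the last.
    """
    if m < 1 or n < m:
        raise ValueError(f"need 1 <= m <= n, got n={n}, m={m}")
    if kind not in _SCHEME_KINDS:
        raise ValueError(f"kind must be one of {_SCHEME_KINDS}, got {kind!r}")
    removals = [0] * m
    where = {"scheme1": 0, "scheme2": (m + 1) // 2 - 1, "scheme3": m - 1}[kind]
    removals[where] = n - m
    return tuple(removals)


def draw_progressive_type2(
    plan: CensoringPlan, p: IERParams, seed=None
) -> np.ndarray:
    """Ordinary progressive Type-II censored sample of size m from the IER model.

    Uses the uniform-spacings construction: with ``tau_i`` iid U(0,1),

        v_i = tau_i ** (1 / (i + R_m + ... + R_{m-i+1})),
        U_i = 1 - v_m v_{m-1} ... v_{m-i+1},

    the ``U_i`` are a progressive Type-II censored U(0,1) sample, and
    ``X_i = F^{-1}(U_i)`` the corresponding IER failure times (ascending).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = plan.m
    removals = np.asarray(plan.removals, dtype=float)
    tau = rng.uniform(size=m)
    # trailing_sum[i-1] = R_m + ... + R_{m-i+1}
    trailing_sum = np.cumsum(removals[::-1])
    v = tau ** (1.0 / (np.arange(1, m + 1) + trailing_sum))
    u = 1.0 - np.cumprod(v[::-1])
    return quantile(u, p)


def truncate_phtics(progressive_times, plan: CensoringPlan) -> PHTICSample:
    """Apply the hybrid Type-I stopping rule to a full progressive sample."""
    x = np.asarray(progressive_times, dtype=float)
    if x.shape != (plan.m,):
        raise ValueError(f"expected {plan.m} progressive failure times")
    if np.any(np.diff(x) < 0):
        raise ValueError("progressive failure times must be sorted")
    if x[-1] < plan.T:
        return PHTICSample(
            times=tuple(x),
            plan=plan,
            case=Case.I,
            C=float(x[-1]),
            removals_applied=plan.removals,
            R_T=0,
        )
    d = int(np.sum(x < plan.T))
    if d == 0:
        raise EmptySampleError(
            f"no failures observed before T={plan.T}; cannot form a sample"
        )
    applied = plan.removals[:d]
    r_t = plan.n - d - sum(applied)
    return PHTICSample(
        times=tuple(x[:d]),
        plan=plan,
        case=Case.II,
        C=float(plan.T),
        removals_applied=applied,
        R_T=r_t,
    )


def assemble_sample(times, plan: CensoringPlan) -> PHTICSample:
    """Build a PHTICSample from observed failure times and the plan.

    The case, termination point and terminal removal are derived: r = m with
    the last failure before T is Case I; r < m is Case II with C = T.
    """
    times = tuple(float(t) for t in times)
    r = len(times)
    if r == 0:
        raise EmptySampleError("no observed failure times")
    if r > plan.m:
        raise ValueError(f"more failures ({r}) than the plan's m={plan.m}")
    if r == plan.m and times[-1] < plan.T:
        return PHTICSample(
            times=times,
            plan=plan,
            case=Case.I,
            C=times[-1],
            removals_applied=plan.removals,
            R_T=0,
        )
    if any(t > plan.T for t in times):
        raise ValueError("observed failures beyond the threshold time T")
    applied = plan.removals[:r]
    return PHTICSample(
        times=times,
        plan=plan,
        case=Case.II,
        C=plan.T,
        removals_applied=applied,
        R_T=plan.n - r - sum(applied),
    )


def generate_phtics(plan: CensoringPlan, p: IERParams, seed=None) -> PHTICSample:
    """Draw a progressive Type-II sample and truncate it at min(X_m, T)."""
    sample = truncate_phtics(draw_progressive_type2(plan, p, seed), plan)
    if isinstance(seed, int):
        object.__setattr__(sample, "seed", seed)
    return sample


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------


class SampleParseError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_sample(path, sample: PHTICSample) -> None:
    """Write a sample as a small text file (header + one failure time per line)."""
    plan = sample.plan
    lines = [
        "# ierph PHT-ICS sample",
        f"n {plan.n}",
        f"m {plan.m}",
        f"T {plan.T!r}",
        "removals " + " ".join(str(r) for r in plan.removals),
        "times",
    ]
    lines += [repr(t) for t in sample.times]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sample(path) -> PHTICSample:
    """Parse a sample file written by :func:`write_sample`."""
    header: dict[str, object] = {}
    times: list[float] = []
    in_times = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if in_times:
                try:
                    times.append(float(line))
                except ValueError:
                    raise SampleParseError(line_no, f"bad failure time {line!r}")
                continue
            key, _, rest = line.partition(" ")
            if key == "times":
                in_times = True
            elif key in ("n", "m"):
                try:
                    header[key] = int(rest)
                except ValueError:
                    raise SampleParseError(line_no, f"bad integer for {key}: {rest!r}")
            elif key == "T":
                try:
                    header[key] = float(rest)
                except ValueError:
                    raise SampleParseError(line_no, f"bad threshold: {rest!r}")
            elif key == "removals":
                try:
                    header[key] = tuple(int(tok) for tok in rest.split())
                except ValueError:
                    raise SampleParseError(line_no, f"bad removals: {rest!r}")
            else:
                raise SampleParseError(line_no, f"unknown header key {key!r}")
    for key in ("n", "m", "T", "removals"):
        if key not in header:
            raise SampleParseError(0, f"missing header line {key!r}")
    plan = CensoringPlan(
        n=header["n"], m=header["m"], removals=header["removals"], T=header["T"]
    )
    return assemble_sample(times, plan)
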