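"""Bundled arthritis relief-time data and its censored sub-samples.

Fifty relief times (hours, recorded to one decimal) of arthritic patients on
a fixed drug dose — a classic complete lifetime dataset — plus the four
artificial PHT-ICS samples drawn from it with m = 25 under different removal
patterns and thresholds, used throughout the real-data workflow.
"""

from __future__ import annotations

import numpy as np

from .censoring import CensoringPlan, PHTICSample, assemble_sample

__all__ = ["relief_times", "table_samples", "censored_sample"]

_RELIEF_TIMES = (
    2.9, 2.9, 3.4, 3.4, 3.5, 3.6, 3.6, 3.6, 4.4, 4.4,
    4.6, 4.6, 4.9, 4.9, 5.0, 5.0, 5.2, 5.4, 5.5, 5.5,
    5.5, 5.6, 5.7, 5.8, 5.9, 5.9, 6.0, 6.0, 6.1, 6.1,
    6.2, 6.4, 6.8, 7.0, 7.0, 7.1, 7.1, 7.1, 7.2, 7.3,
    7.5, 7.5, 8.0, 8.0, 8.1, 8.2, 8.4, 8.4, 8.4, 8.7,
)

# (removals, T, observed failure times)
_CENSORED = {
    "S1": (
        (1,) * 25,
        7.4,
        (2.9, 3.4, 3.5, 3.6, 4.4, 4.6, 4.9, 5.0, 5.2, 5.5,
         5.5, 5.7, 5.9, 6.0, 6.1, 6.2, 6.8, 7.0, 7.1, 7.2),
    ),
    "S2": (
        (25,) + (0,) * 24,
        8.5,
        (2.9, 3.4, 3.5, 3.6, 4.4, 4.6, 4.9, 5.0, 5.5, 5.7,
         5.8, 5.9, 6.0, 6.0, 6.1, 6.2, 6.4, 6.8, 7.1, 7.2,
         7.3, 7.5, 7.5, 8.0, 8.1),
    ),
    "S3": (
        (0,) * 12 + (25,) + (0,) * 12,
        6.9,
        (2.9, 2.9, 3.4, 3.4, 3.5, 3.6, 3.6, 3.6, 4.4, 4.4,
         4.6, 4.6, 4.9, 4.9, 5.0, 5.4, 5.5, 5.5, 5.7, 6.1, 6.8),
    ),
    "S4": (
        (0,) * 24 + (25,),
        6.1,
        (2.9, 2.9, 3.4, 3.4, 3.5, 3.6, 3.6, 3.6, 4.4, 4.4,
         4.6, 4.6, 4.9, 4.9, 5.0, 5.0, 5.2, 5.4, 5.5, 5.5,
         5.5, 5.6, 5.7, 5.8, 5.9),
    ),
}


def relief_times() -> np.ndarray:
    """The 50 complete relief times, ascending."""
    return np.asarray(_RELIEF_TIMES, dtype=float)


def table_samples() -> tuple[str, ...]:
    """Names of the bundled censored samples."""
    return tuple(_CENSORED)


def censored_sample(name: str) -> PHTICSample:
    """One of the four bundled PHT-ICS samples ('S1'..'S4')."""
    try:
        removals, threshold, times = _CENSORED[name]
    except KeyError:
        raise KeyError(f"unknown sample {name!r}; choose from {table_samples()}")
    plan = CensoringPlan(n=50, m=25, removals=removals, T=threshold)
    return assemble_sample(times, plan)
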