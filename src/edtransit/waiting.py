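"""Expected waiting time from departure probabilities and odds ratios.

If the queue is in steady state the number of 30-minute intervals a
patient waits before departing is geometric with success probability p,
so the expected waiting time in hours is

    WT = 0.5 * (1 - p) / p,

with 0.5 h being the interval length. For two scenarios with departure
probabilities p0 and p1, WT0 / WT1 equals the odds ratio of scenario 1
versus scenario 0 — the reciprocal odds ratio is the multiplicative change
in expected waiting time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

#: Grid interval length in hours; the 0.5 factor of the waiting-time formula.
DEFAULT_INTERVAL_HOURS = 0.5


@dataclass(frozen=True)
class WTScenario:
    """A covariate configuration with its departure probability and wait."""

    covariates: dict[str, float]
    logit: float
    p: float
    wt_hours: float

    def wt_minutes(self) -> float:
        return self.wt_hours * 60.0

    def __str__(self) -> str:
        h = int(self.wt_hours)
        m = int(round((self.wt_hours - h) * 60))
        return (
            f"logit={self.logit:.3f}  p={self.p:.4f}  "
            f"WT={self.wt_hours:.2f} h ({h}:{m:02d})"
        )


def wt_from_p(p: float, interval_hours: float = DEFAULT_INTERVAL_HOURS) -> float:
    """Expected waiting time in hours for departure probability ``p``.

    Raises for p <= 0: a zero departure probability implies an infinite
    wait, outside the model's domain.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"departure probability must be in (0, 1], got {p}")
    return interval_hours * (1.0 - p) / p


def wt_from_scenario(
    coefficients: Mapping[str, float],
    scenario: Mapping[str, float] | None = None,
    interval_hours: float = DEFAULT_INTERVAL_HOURS,
) -> WTScenario:
    """Waiting time for a covariate scenario under fitted coefficients.

    ``coefficients`` must contain ``intercept``; covariates absent from the
    scenario default to zero (the weekday-day, empty-queue reference).
    Algebraically WT = interval_hours * exp(-logit).
    """
    scenario = dict(scenario or {})
    if "intercept" not in coefficients:
        raise ValueError("coefficients must include 'intercept'")
    unknown = [k for k in scenario if k not in coefficients or k == "intercept"]
    if unknown:
        raise ValueError(f"unknown covariate names in scenario: {unknown}")
    logit = float(coefficients["intercept"])
    for name, value in scenario.items():
        logit += float(coefficients[name]) * float(value)
    p = float(expit(logit))
    return WTScenario(scenario, logit, p, wt_from_p(p, interval_hours))


def wt_ratio_from_or(odds_ratio: float) -> tuple[float, int]:
    """Waiting-time multiplier per unit covariate increase, from its OR.

    Returns (ratio, percent) with ratio = 1/OR and percent = round(100*ratio);
    e.g. an arrival OR of 0.942 lengthens the expected wait by a factor
    1.062, printed as 106%.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    ratio = 1.0 / odds_ratio
    return ratio, int(round(100.0 * ratio))


def incremental_wt(
    wt0_minutes: float, odds_ratio: float, k: int, mode: str = "linear"
) -> float:
    """Total expected waiting time in minutes after ``k`` unit increases.

    ``linear`` adds k copies of the single-step increment
    wt0 * (1/OR - 1) to the baseline — e.g. a two-hour baseline gains about
    7 minutes per additional arrival in the interval. ``compound`` applies
    the multiplier k times: wt0 * (1/OR)**k. Both return wt0 at k = 0 and
    agree to first order in (1/OR - 1).
    """
    if wt0_minutes < 0 or k < 0:
        raise ValueError("baseline waiting time and k must be non-negative")
    ratio = 1.0 / odds_ratio
    if mode == "linear":
        return wt0_minutes + k * wt0_minutes * (ratio - 1.0)
    if mode == "compound":
        return wt0_minutes * ratio**k
    raise ValueError(f"mode must be 'linear' or 'compound', got {mode!r}")
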