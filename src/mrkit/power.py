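"""Analytic power for two-sample MR with a continuous outcome.

The IVW estimator's sampling variance with instruments explaining a
fraction R^2 of the exposure variance in an outcome sample of size n is
approximately 1 / (n * R^2) on the standardized scale, so the two-sided
test of a causal effect beta has power

    Phi(|beta| * sqrt(n * R^2) - z_{1-alpha/2})

with Phi the standard normal CDF. Effects specified as odds ratios enter
as beta = ln(OR) per SD of exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError


@dataclass
class PowerSpec:
    """Inputs for one analytic power evaluation."""

    n_outcome: float
    r2_exposure: float
    effect: float  # ln(OR) per SD of exposure
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome <= 0:
            raise DomainError("n_outcome must be positive")
        if not (0.0 < self.r2_exposure < 1.0):
            raise DomainError("r2_exposure must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError("alpha must lie in (0, 1)")


def or_to_beta(or_: float) -> float:
    """ln(OR); the effect scale used throughout."""
    if or_ <= 0:
        raise DomainError("odds ratio must be positive")
    return float(np.log(or_))


def mr_power(spec: PowerSpec) -> float:
    """Analytic power in [0, 1] for the given scenario."""
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(spec.effect) * np.sqrt(spec.n_outcome * spec.r2_exposure)
    return float(stats.norm.cdf(ncp - z_crit))


def power_percent(spec: PowerSpec) -> int:
    """Power rounded to the nearest whole percent (display convention)."""
    return int(round(100.0 * mr_power(spec)))


def power_table(
    n_outcome: float,
    r2_exposure: float,
    odds_ratios,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power for a list of odds ratios (columns: OR, beta, power, power_pct)."""
    rows = []
    for or_ in odds_ratios:
        beta = or_to_beta(or_)
        spec = PowerSpec(n_outcome=n_outcome, r2_exposure=r2_exposure,
                         effect=beta, alpha=alpha)
        p = mr_power(spec)
        rows.append({"OR": or_, "beta": beta, "power": p,
                     "power_pct": int(round(100 * p))})
    return pd.DataFrame(rows)
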