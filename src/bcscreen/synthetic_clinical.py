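"""Synthetic clinical fixtures.

The estimation stage was developed against a clinical series of 187
breast-cancer patients (tumor size, BMI, age) that is not publicly
deposited.  This module generates synthetic stand-ins that match the
published marginal summaries (truncated-normal marginals with the reported
means, SDs and ranges) joined by a Gaussian copula, plus growth-rate
observations drawn from the gamma regression itself for parameter-recovery
testing.  The fixtures emulate marginal moments only; they are not the real
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .natural_history import GrowthModel
from .population import BmiScenario

__all__ = ["ClinicalFixtureSpec", "generate_clinical_fixture", "generate_growth_observations"]


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal marginal whose *truncated* moments match (mean, sd).

    The published mean/sd describe the observed (bounded) variable, so the
    underlying normal's location and scale are solved numerically to make
    the truncated distribution reproduce them.
    """

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.lower < self.upper:
            raise ValueError("infeasible bounds")
        if not self.lower < self.mean < self.upper:
            raise ValueError("infeasible bounds: mean outside (lower, upper)")

    def _matched(self):
        def gap(params):
            loc, log_scale = params
            scale = np.exp(log_scale)
            a = (self.lower - loc) / scale
            b = (self.upper - loc) / scale
            d = stats.truncnorm(a, b, loc=loc, scale=scale)
            return [d.mean() - self.mean, d.std() - self.sd]

        from scipy import optimize

        sol = optimize.fsolve(gap, [self.mean, np.log(self.sd)], full_output=False)
        loc, scale = sol[0], float(np.exp(sol[1]))
        return loc, scale

    def ppf(self, q):
        loc, scale = self._matched()
        a = (self.lower - loc) / scale
        b = (self.upper - loc) / scale
        return stats.truncnorm.ppf(q, a, b, loc=loc, scale=scale)


@dataclass(frozen=True)
class ClinicalFixtureSpec:
    """Marginal summaries of the clinical series to emulate."""

    n: int = 187
    tumor_size: Marginal = field(default_factory=lambda: Marginal(51.38, 30.35, 10.0, 130.0))
    bmi: Marginal = field(default_factory=lambda: Marginal(29.73, 7.46, 14.96, 67.46))
    age: Marginal = field(default_factory=lambda: Marginal(51.0, 12.0, 26.0, 85.0))
    correlation_bmi_size: float = 0.1

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not -1 < self.correlation_bmi_size < 1:
            raise ValueError("correlation must lie in (-1, 1)")


def generate_clinical_fixture(
    spec: ClinicalFixtureSpec = ClinicalFixtureSpec(),
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic (tumor_size_mm, bmi, age) table with copula-linked marginals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = spec.correlation_bmi_size
    cov = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    z = rng.multivariate_normal(np.zeros(3), cov, size=spec.n)
    u = stats.norm.cdf(z)
    return pd.DataFrame(
        {
            "tumor_size_mm": spec.tumor_size.ppf(u[:, 0]),
            "bmi": spec.bmi.ppf(u[:, 1]),
            "age": spec.age.ppf(u[:, 2]),
        }
    )


def generate_growth_observations(
    growth: GrowthModel,
    scenario: BmiScenario,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """(bmi, growth_rate) pairs drawn from the gamma regression."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bmi = scenario.distribution().rvs(size=n, random_state=rng)
    r = growth.sample(bmi, rng)
    return pd.DataFrame({"bmi": bmi, "growth_rate": r})
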