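"""Birth cohorts and BMI populations.

The disease population is a stack of yearly birth cohorts; each woman carries
a body-mass index drawn from a truncated normal distribution.  Scenario
presets cover the four WHO BMI categories (each concentrated within its band)
and a heterogeneous "general" population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "BmiScenario",
    "BMI_SCENARIOS",
    "generate_population",
    "bmi_category",
    "BMI_CATEGORIES",
]

#: WHO category cut points (kg/m^2); intervals are left-closed/right-open.
BMI_CUTS = (18.5, 25.0, 30.0)
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


@dataclass(frozen=True)
class CohortSpec:
    """Yearly birth cohorts of equal size.

    Parameters
    ----------
    first_birth_year, last_birth_year : int
        Inclusive calendar range of birth years.
    births_per_cohort : int
        Number of births simulated into each yearly cohort.
    """

    first_birth_year: int = 1986
    last_birth_year: int = 2020
    births_per_cohort: int = 5000

    def __post_init__(self) -> None:
        if self.last_birth_year < self.first_birth_year:
            raise ValueError("last_birth_year must be >= first_birth_year")
        if self.births_per_cohort <= 0:
            raise ValueError("births_per_cohort must be positive")

    @property
    def n_cohorts(self) -> int:
        return self.last_birth_year - self.first_birth_year + 1

    @property
    def size(self) -> int:
        return self.n_cohorts * self.births_per_cohort


@dataclass(frozen=True)
class BmiScenario:
    """Truncated-normal BMI distribution for a study population.

    The default truncation bounds (10, 80) keep sampled values physiologic;
    category presets concentrate the distribution well inside one WHO band.
    """

    label: str
    mean: float
    sd: float
    lower_bound: float = 10.0
    upper_bound: float = 80.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be below upper_bound")
        if not self.lower_bound < self.mean < self.upper_bound:
            raise ValueError("mean must lie inside the truncation bounds")

    def distribution(self) -> stats.rv_continuous:
        a = (self.lower_bound - self.mean) / self.sd
        b = (self.upper_bound - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)


#: Scenario presets: (mean, sd) pairs for the category populations and the
#: heterogeneous general population.
BMI_SCENARIOS = {
    "underweight": BmiScenario("underweight", 15.0, 0.50),
    "normal": BmiScenario("normal", 21.5, 0.50),
    "overweight": BmiScenario("overweight", 28.5, 0.50),
    "obese": BmiScenario("obese", 45.0, 2.50),
    "general": BmiScenario("general", 25.0, 3.0),
}


def bmi_category(bmi):
    """Map BMI (kg/m^2) to its WHO category label.

    Accepts a scalar or array; intervals are left-closed/right-open on the
    cut points 18.5, 25.0 and 30.0, so 18.5 -> "normal" and 30.0 -> "obese".
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("BMI must be positive and finite")
    idx = np.searchsorted(BMI_CUTS, arr, side="right")
    out = np.asarray(BMI_CATEGORIES, dtype=object)[idx]
    if np.isscalar(bmi) or arr.ndim == 0:
        return str(out if arr.ndim == 0 else out[0])
    return out


def generate_population(
    cohorts: CohortSpec,
    scenario: BmiScenario,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the disease population for one scenario.

    Returns a DataFrame with one row per woman and columns
    ``id, birth_year, bmi, bmi_category``; exactly ``births_per_cohort``
    rows per birth year.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = cohorts.size
    birth_year = np.repeat(
        np.arange(cohorts.first_birth_year, cohorts.last_birth_year + 1),
        cohorts.births_per_cohort,
    )
    bmi = scenario.distribution().rvs(size=n, random_state=rng)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "birth_year": birth_year,
            "bmi": bmi,
            "bmi_category": pd.Categorical(bmi_category(bmi), categories=BMI_CATEGORIES),
        }
    )
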