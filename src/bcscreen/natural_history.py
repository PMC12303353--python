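"""Breast-cancer natural-history model.

The disease model composes four sub-models:

* **Onset** — a two-stage clonal-expansion (MVK) survival function
  ``F_T(t) = [(B-A) e^{Bt} / (B e^{(B-A)t} - A)]^delta`` reparameterized from
  the four Poisson event rates.  Onset ages are sampled on a yearly grid with
  a distinguished "never" outcome, and the incidence-rate adjustment for a
  lower-incidence population maps the reference-grid age ``t`` to an attained
  onset age ``age_scale * t`` (default 0.48, the West Africa / Northern
  Europe age-standardized incidence ratio).
* **Growth** — exponential volume growth ``V(z) = v0 * exp(z / r)`` with the
  inverse growth rate ``r`` (years) gamma-distributed across women; the mean
  follows a log-linear link in BMI, ``E(R) = exp(lambda0 + lambda1 * bmi)``,
  with squared coefficient of variation ``phi`` (``Var(R) = phi * E(R)^2``).
  The tumor is spherical with onset diameter 0.5 mm.
* **Symptomatic detection** — a hazard proportional to current tumor volume,
  ``h(s) = eta * V(s)``; the exact inverse-CDF of this hazard gives the
  volume, size and time at symptomatic detection in closed form.
* **Convention switch** — ``inverse_rate`` (the default; r is a time
  constant, doubling time ``DT = r ln 2``) or ``direct_rate`` (r multiplies
  the exponent, ``DT = ln 2 / r``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "MvkRates",
    "reparameterize_mvk",
    "OnsetModel",
    "GrowthModel",
    "TumorGeometry",
    "SymptomaticModel",
    "NaturalHistoryModel",
    "volume_from_diameter",
    "diameter_from_volume",
    "tumor_volume",
    "doubling_time",
    "sample_symptomatic",
    "simulate_life_histories",
]

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# MVK onset model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MvkRates:
    """Poisson event rates of the two-stage clonal-expansion model."""

    cell_division_rate: float   # alpha~
    first_event_rate: float     # nu~
    cell_death_rate: float      # beta~
    second_event_rate: float    # mu~

    def __post_init__(self) -> None:
        for name in (
            "cell_division_rate",
            "first_event_rate",
            "cell_death_rate",
            "second_event_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def reparameterize_mvk(rates: MvkRates) -> tuple[float, float, float]:
    """Map the four MVK event rates to the identifiable triple (A, B, delta).

    ``A`` and ``B`` are the two roots ``(c ± sqrt(c^2 + 4 alpha mu)) / 2`` of
    the quadratic ``x^2 - c x - alpha mu`` with ``c = beta + mu - alpha``
    (A takes the + branch), and ``delta = nu / alpha``.
    """
    alpha = rates.cell_division_rate
    if alpha <= 0:
        raise ValueError("cell_division_rate must be positive")
    c = rates.cell_death_rate + rates.second_event_rate - alpha
    disc = c * c + 4.0 * alpha * rates.second_event_rate
    if disc < 0:
        raise ValueError("negative discriminant in MVK reparameterization")
    root = np.sqrt(disc)
    A = 0.5 * (c + root)
    B = 0.5 * (c - root)
    delta = rates.first_event_rate / alpha
    return A, B, delta


@dataclass(frozen=True)
class OnsetModel:
    """Onset-age distribution on a yearly reference grid.

    ``survival(t)`` evaluates the MVK survival function at reference age
    ``t``.  Sampling weights are the interval masses of the survival over the
    reference grid (default 38..92); the residual mass beyond the last grid
    age, together with the mass below the first, is assigned to the "never"
    outcome.  The attained onset age is ``age_scale`` times the sampled
    reference-grid age, reflecting earlier risk attainment in the target
    population.

    ``scale_applies_to`` selects where the incidence adjustment acts:
    ``"onset_age"`` (default; weights from the unscaled survival, onset age
    scaled) or ``"evaluation"`` (weights from the survival at scaled ages,
    grid ages attained unscaled).
    """

    A: float = -0.0722
    B: float = 1.18e-3
    delta: float = 0.0952
    age_scale: float = 0.48
    grid: tuple = tuple(range(38, 93))
    scale_applies_to: str = "onset_age"

    def __post_init__(self) -> None:
        if self.B <= self.A:
            raise ValueError("requires B > A")
        if not 0 < self.age_scale <= 1:
            raise ValueError("age_scale must be in (0, 1]")
        if len(self.grid) == 0:
            raise ValueError("empty onset grid")
        if list(self.grid) != sorted(self.grid):
            raise ValueError("onset grid must be increasing")
        if self.scale_applies_to not in ("onset_age", "evaluation"):
            raise ValueError("scale_applies_to must be 'onset_age' or 'evaluation'")

    def survival(self, t) -> np.ndarray:
        """MVK survival F_T(t) = P(T > t) at reference age t (vectorized).

        Evaluated in log space so that large ``(B - A) * t`` cannot overflow.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("age must be non-negative")
        A, B, d = self.A, self.B, self.delta
        # log F = delta * [log(B-A) + B t - log(B e^{(B-A)t} - A)]
        #       = delta * [log(B-A) + B t - (B-A) t - log(B - A e^{-(B-A)t})]
        e = (B - A) * t
        denom = B - A * np.exp(-e)
        if np.any(denom <= 0):
            raise FloatingPointError("survival denominator non-positive")
        logF = d * (np.log(B - A) + B * t - e - np.log(denom))
        return np.exp(logF)

    def onset_probabilities(self) -> tuple[np.ndarray, float]:
        """Normalized sampling weights over the grid, and the "never" weight.

        The weight at grid age ``t`` is the survival mass on the year
        ``(t - 1, t]``; "never" collects the residual, so the weights sum
        to one exactly.
        """
        grid = np.asarray(self.grid, dtype=float)
        s = self.age_scale if self.scale_applies_to == "evaluation" else 1.0
        upper = self.survival(s * grid)
        lower = self.survival(s * (grid - 1))
        w = lower - upper
        w = np.clip(w, 0.0, None)
        total_onset = w.sum()
        never = 1.0 - total_onset
        return w / (total_onset + never), never / (total_onset + never)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n attained onset ages; NaN encodes "never"."""
        w, never = self.onset_probabilities()
        grid = np.asarray(self.grid, dtype=float)
        if self.scale_applies_to == "onset_age":
            ages = self.age_scale * grid
        else:
            ages = grid
        support = np.concatenate([[np.nan], ages])
        probs = np.concatenate([[never], w])
        idx = rng.choice(len(support), size=n, p=probs)
        return support[idx]


# ---------------------------------------------------------------------------
# Growth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthModel:
    """Gamma-distributed growth rate with a log-linear BMI link.

    ``lambda0`` and ``lambda1`` define the mean link
    ``E(R) = exp(lambda0 + lambda1 * bmi)``; ``phi`` is the squared
    coefficient of variation, so the gamma shape is ``1 / phi`` and
    ``Var(R) = phi * E(R)^2``.
    """

    lambda0: float = -0.015
    lambda1: float = 0.009
    phi: float = 1.355
    convention: str = "inverse_rate"

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.convention not in ("inverse_rate", "direct_rate"):
            raise ValueError("convention must be 'inverse_rate' or 'direct_rate'")

    def mean_from_bmi(self, bmi) -> np.ndarray:
        bmi = np.asarray(bmi, dtype=float)
        if np.any(bmi <= 0):
            raise ValueError("BMI must be positive")
        return np.exp(self.lambda0 + self.lambda1 * bmi)

    def sample(self, bmi, rng: np.random.Generator) -> np.ndarray:
        """Draw one growth rate per BMI value (shape 1/phi, mean from link)."""
        mu = self.mean_from_bmi(bmi)
        shape = 1.0 / self.phi
        return rng.gamma(shape, mu * self.phi, size=np.shape(mu))


# ---------------------------------------------------------------------------
# Geometry and detection hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorGeometry:
    """Spherical tumor geometry; onset diameter 0.5 mm (v0 ~ 0.065 mm^3)."""

    onset_diameter: float = 0.5

    def __post_init__(self) -> None:
        if self.onset_diameter <= 0:
            raise ValueError("onset_diameter must be positive")

    @property
    def onset_volume(self) -> float:
        return np.pi * self.onset_diameter ** 3 / 6.0


@dataclass(frozen=True)
class SymptomaticModel:
    """Symptomatic-detection hazard eta * V(t) (eta per mm^3 per year)."""

    eta: float = 6.418e-5

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")


def volume_from_diameter(d):
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    return np.pi * d ** 3 / 6.0


def diameter_from_volume(v):
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    return (6.0 * v / np.pi) ** (1.0 / 3.0)


def tumor_volume(geometry: TumorGeometry, r, onset_age, age, convention="inverse_rate"):
    """Tumor volume (mm^3) at a given age for onset at ``onset_age``."""
    r = np.asarray(r, dtype=float)
    z = np.asarray(age, dtype=float) - np.asarray(onset_age, dtype=float)
    if np.any(z < 0):
        raise ValueError("age must be at or after onset")
    if np.any(r <= 0):
        raise ValueError("growth rate must be positive")
    expo = z / r if convention == "inverse_rate" else z * r
    return geometry.onset_volume * np.exp(expo)


def doubling_time(r, convention="inverse_rate"):
    """Tumor volume doubling time in days."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("growth rate must be positive")
    if convention == "inverse_rate":
        return r * np.log(2.0) * DAYS_PER_YEAR
    return np.log(2.0) / r * DAYS_PER_YEAR


def sample_symptomatic(
    geometry: TumorGeometry,
    symptomatic: SymptomaticModel,
    r,
    onset_age,
    u,
    convention="inverse_rate",
):
    """Invert the volume-proportional symptomatic hazard.

    For the hazard ``eta * V(s)`` with exponential growth, the cumulative
    hazard from onset is ``eta * r * (V(s) - v0)`` (inverse-rate convention),
    so for a uniform draw ``u`` the symptomatic volume is
    ``V(U) = v0 + (-ln(1-u)) / (eta * r)`` and the sojourn
    ``U' = r * ln(V(U)/v0)``.  Under the direct-rate convention the roles of
    ``r`` flip: ``V(U) = v0 + r * (-ln(1-u)) / eta`` and
    ``U' = ln(V(U)/v0) / r``.

    Returns ``(V(U), d(U), U', U)``.
    """
    u = np.asarray(u, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    if np.any(r <= 0):
        raise ValueError("growth rate must be positive")
    v0 = geometry.onset_volume
    cumhaz = -np.log1p(-u)
    if convention == "inverse_rate":
        vU = v0 + cumhaz / (symptomatic.eta * r)
        sojourn = r * np.log(vU / v0)
    else:
        vU = v0 + r * cumhaz / symptomatic.eta
        sojourn = np.log(vU / v0) / r
    dU = diameter_from_volume(vU)
    return vU, dU, sojourn, np.asarray(onset_age, dtype=float) + sojourn


# ---------------------------------------------------------------------------
# Composite simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NaturalHistoryModel:
    """Bundle of the four sub-models used by the simulators."""

    onset: OnsetModel = field(default_factory=OnsetModel)
    growth: GrowthModel = field(default_factory=GrowthModel)
    geometry: TumorGeometry = field(default_factory=TumorGeometry)
    symptomatic: SymptomaticModel = field(default_factory=SymptomaticModel)

    @property
    def convention(self) -> str:
        return self.growth.convention


def simulate_life_histories(
    population: pd.DataFrame,
    model: NaturalHistoryModel,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the natural history (no screening) for a population.

    Adds, per woman: onset age (NaN = never develops a tumor), inverse growth
    rate ``r``, doubling time in days, symptomatic volume/diameter, sojourn
    ``U'`` and symptomatic age ``U``; downstream fields are NaN for women
    without onset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(population)
    out = population.reset_index(drop=True).copy()

    onset_age = model.onset.sample(n, rng)
    has = ~np.isnan(onset_age)

    r = np.full(n, np.nan)
    r[has] = model.growth.sample(out.loc[has, "bmi"].to_numpy(), rng)
    u = rng.uniform(size=int(has.sum()))

    vU = np.full(n, np.nan)
    dU = np.full(n, np.nan)
    sojourn = np.full(n, np.nan)
    sympt_age = np.full(n, np.nan)
    vU[has], dU[has], sojourn[has], sympt_age[has] = sample_symptomatic(
        model.geometry,
        model.symptomatic,
        r[has],
        onset_age[has],
        u,
        model.convention,
    )

    dt = np.full(n, np.nan)
    dt[has] = doubling_time(r[has], model.convention)

    out["onset_age"] = onset_age
    out["growth_rate"] = r
    out["doubling_time_days"] = dt
    out["sympt_volume"] = vU
    out["sympt_diameter"] = dU
    out["sojourn"] = sojourn
    out["sympt_age"] = sympt_age
    return out
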