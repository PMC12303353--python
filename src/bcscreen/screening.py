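"""Mammography screening superimposed on simulated natural histories.

A screening program is a schedule of exact ages (start, start + interval,
... <= end), an attendance mixture (a woman belongs permanently to a
participation group and attends each scheduled screen independently with her
group's probability), and a logistic size-sensitivity
``P(detect | tumor of diameter d) = logistic(beta0 + beta1 * d)`` (zero when
no tumor exists).  Screening is conditioned on the natural history in the
absence of screening: a woman's tumor onset, growth rate and latent
symptomatic age are fixed inputs, and screens compete with the symptomatic
age for detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .natural_history import NaturalHistoryModel, diameter_from_volume

__all__ = [
    "ScreeningPolicy",
    "AttendanceModel",
    "SensitivityModel",
    "SENSITIVITY_PROFILES",
    "screen_sensitivity",
    "assign_attendance",
    "run_screening",
    "MODES",
]

#: Detection-outcome labels.  ``symptomatic_outside_program`` covers
#: symptomatic diagnoses that are not interval cancers (no prior attended
#: negative screen, or symptomatic after the program ends but before the
#: follow-up horizon); ``excluded`` marks loss to follow-up.
MODES = ("screen", "interval", "symptomatic_outside_program", "none", "excluded")


@dataclass(frozen=True)
class ScreeningPolicy:
    """Screening schedule: ages start, start+interval, ... <= end."""

    start_age: float = 30.0
    end_age: float = 65.0
    interval_months: int = 24

    def __post_init__(self) -> None:
        if not self.start_age < self.end_age:
            raise ValueError("start_age must be below end_age")
        if self.interval_months <= 0:
            raise ValueError("interval_months must be positive")

    @property
    def interval_years(self) -> float:
        return self.interval_months / 12.0

    def schedule(self) -> np.ndarray:
        ages = np.arange(self.start_age, self.end_age + 1e-9, self.interval_years)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("screening schedule must be strictly increasing")
        return ages


@dataclass(frozen=True)
class AttendanceModel:
    """Mixture of participation groups with per-screen attendance.

    ``groups`` is a list of ``(population_share, per_screen_probability)``;
    the default imperfect mixture is 80% of women attending each screen with
    probability 0.90 and 20% with probability 0.15.
    """

    mode: str = "imperfect"
    groups: tuple = ((0.8, 0.90), (0.2, 0.15))

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "imperfect"):
            raise ValueError("mode must be 'perfect' or 'imperfect'")
        shares = [g[0] for g in self.groups]
        probs = [g[1] for g in self.groups]
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("group shares must sum to 1")
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("attendance probabilities must lie in [0, 1]")

    def per_screen_probability(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Assign each woman a permanent group; return her per-screen probability."""
        if self.mode == "perfect":
            return np.ones(n)
        shares = np.array([g[0] for g in self.groups])
        probs = np.array([g[1] for g in self.groups])
        g = rng.choice(len(shares), size=n, p=shares)
        return probs[g]


@dataclass(frozen=True)
class SensitivityModel:
    """Logistic screening sensitivity in tumor diameter (mm)."""

    beta0: float = -5.04
    beta1: float = 0.56

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError("beta1 must be positive (larger tumors more detectable)")


#: Named sensitivity profiles: P = 0.5 at 9.0 mm (moderate) / ~7.2 mm (high).
SENSITIVITY_PROFILES = {
    "moderate": SensitivityModel(-5.04, 0.56),
    "high": SensitivityModel(-4.67, 0.65),
}


def screen_sensitivity(model: SensitivityModel, diameter) -> np.ndarray:
    """Per-screen detection probability for an existing tumor of diameter d.

    Returns 0 where ``diameter`` is 0 or NaN (no tumor at the screen).
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("diameter must be non-negative")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-(model.beta0 + model.beta1 * d)))
    return np.where(np.isnan(d) | (d <= 0), 0.0, p)


def assign_attendance(
    model: AttendanceModel,
    n: int,
    n_screens: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean (n, n_screens) attendance matrix; groups fixed per woman."""
    p = model.per_screen_probability(n, rng)
    return rng.uniform(size=(n, n_screens)) < p[:, None]


@dataclass(frozen=True)
class ScreeningProgram:
    """Policy + attendance + sensitivity, with optional BMI stratification.

    ``sensitivity_by_category`` overrides the base sensitivity for specific
    BMI categories (e.g. the high profile for obese women in the BMI
    risk-based program).
    """

    policy: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    attendance: AttendanceModel = field(default_factory=AttendanceModel)
    sensitivity: SensitivityModel = SENSITIVITY_PROFILES["moderate"]
    sensitivity_by_category: dict = field(default_factory=dict)

    def beta_arrays(self, categories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b0 = np.full(len(categories), self.sensitivity.beta0)
        b1 = np.full(len(categories), self.sensitivity.beta1)
        for cat, model in self.sensitivity_by_category.items():
            mask = categories == cat
            b0[mask] = model.beta0
            b1[mask] = model.beta1
        return b0, b1


def run_screening(
    histories: pd.DataFrame,
    program: ScreeningProgram,
    model: NaturalHistoryModel,
    seed: int | np.random.Generator | None = None,
    followup_age: float | None = None,
    cohort: str = "onset_in_program",
    interval_requires_tumor_present: bool = False,
) -> pd.DataFrame:
    """Classify each woman's detection outcome under a screening program.

    Scheduled screens are visited in order; at each screen a woman attends
    according to her participation group, and an attended screen with an
    existing pre-symptomatic tumor detects it with probability
    ``logistic(beta0 + beta1 * d(x))`` via an independent Bernoulli draw.
    The first positive screen before the latent symptomatic age yields
    ``mode="screen"``.  Women who reach their symptomatic age undetected are
    ``interval`` if they had at least one prior attended negative screen
    (optionally required to have occurred while the tumor existed) and
    symptomatic by ``followup_age``, else ``symptomatic_outside_program``.
    Tumors neither detected nor symptomatic by the horizon are ``none``.

    ``cohort`` selects the analysis population: ``onset_in_program`` keeps
    women whose tumor onset falls within [start_age, end_age] (the default,
    matching the program's eligible disease population);
    ``symptomatic_after_start`` keeps any onset but excludes women
    symptomatic before the program start (loss to follow-up).  Excluded
    women get ``mode="excluded"``; women without onset get ``mode="none"``.

    Returns a DataFrame indexed like ``histories`` with columns ``mode``,
    ``detection_age``, ``detection_diameter``, ``n_negative_screens`` (any
    attended negative screens before detection/symptoms) and
    ``n_negative_screens_tumor_present``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    policy = program.policy
    if followup_age is None:
        followup_age = policy.end_age
    if followup_age < policy.end_age:
        raise ValueError("followup_age must not precede the end of screening")
    if cohort not in ("onset_in_program", "symptomatic_after_start"):
        raise ValueError("unknown cohort rule")

    n = len(histories)
    onset = histories["onset_age"].to_numpy(dtype=float)
    r = histories["growth_rate"].to_numpy(dtype=float)
    U = histories["sympt_age"].to_numpy(dtype=float)
    cats = histories["bmi_category"].to_numpy(dtype=object)

    has_onset = ~np.isnan(onset)
    if cohort == "onset_in_program":
        eligible = has_onset & (onset >= policy.start_age) & (onset <= policy.end_age)
    else:
        eligible = has_onset & (U >= policy.start_age)
    excluded = has_onset & ~eligible

    schedule = policy.schedule()
    attendance = assign_attendance(program.attendance, n, len(schedule), rng)
    b0, b1 = program.beta_arrays(cats)

    v0 = model.geometry.onset_volume
    inverse = model.convention == "inverse_rate"

    detected = np.zeros(n, dtype=bool)
    det_age = np.full(n, np.nan)
    det_diam = np.full(n, np.nan)
    n_neg_any = np.zeros(n, dtype=int)
    n_neg_tum = np.zeros(n, dtype=int)

    for k, x in enumerate(schedule):
        att = attendance[:, k]
        active = eligible & ~detected & att & (U > x)
        tumor = active & (onset <= x)
        d = np.zeros(n)
        if tumor.any():
            z = x - onset[tumor]
            expo = z / r[tumor] if inverse else z * r[tumor]
            d[tumor] = diameter_from_volume(v0 * np.exp(expo))
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-(b0 + b1 * d)))
        hit = tumor & (rng.uniform(size=n) < p)
        detected |= hit
        det_age[hit] = x
        det_diam[hit] = d[hit]
        neg = active & ~hit
        n_neg_any[neg] += 1
        n_neg_tum[neg & tumor] += 1

    sympt = eligible & ~detected & (U <= followup_age)
    n_prior = n_neg_tum if interval_requires_tumor_present else n_neg_any
    interval = sympt & (n_prior > 0)
    outside = sympt & ~interval

    mode = np.full(n, "none", dtype=object)
    mode[excluded] = "excluded"
    mode[detected & eligible] = "screen"
    mode[interval] = "interval"
    mode[outside] = "symptomatic_outside_program"

    det_age_out = det_age.copy()
    det_diam_out = det_diam.copy()
    sympt_any = interval | outside
    det_age_out[sympt_any] = U[sympt_any]
    det_diam_out[sympt_any] = histories["sympt_diameter"].to_numpy(dtype=float)[sympt_any]

    return pd.DataFrame(
        {
            "id": histories["id"].to_numpy(),
            "mode": pd.Categorical(mode, categories=MODES),
            "detection_age": det_age_out,
            "detection_diameter": det_diam_out,
            "n_negative_screens": n_neg_any,
            "n_negative_screens_tumor_present": n_neg_tum,
            "eligible": eligible,
        },
        index=histories.index,
    )
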