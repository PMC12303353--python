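"""Descriptive summaries of simulated screening programs.

Aggregates paired no-screening / screening runs into the program-comparison
table (% change, % overdiagnosis, detection-mode shares), the tumor-size
band distribution, doubling-time summaries by BMI category and detection
mode, and presence-time (sojourn) summaries for interval cancers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProgramSummary",
    "summarize_program",
    "size_distribution",
    "doubling_time_summary",
    "presence_time_summary",
    "SIZE_BANDS",
]

#: Diameter bands in mm, left-closed/right-open.
SIZE_BANDS = ((0, 10), (10, 20), (20, 50), (50, np.inf))
SIZE_BAND_LABELS = ("0-9 mm", "10-19 mm", "20-50 mm", ">=50 mm")

DIAGNOSED_MODES = ("screen", "interval", "symptomatic_outside_program")


@dataclass(frozen=True)
class ProgramSummary:
    """Program-comparison row for one scenario."""

    scenario: str
    n_diagnosed_no_screening: int
    n_diagnosed_screening: int
    n_screen_detected: int
    n_interval: int

    def __post_init__(self) -> None:
        if self.n_diagnosed_no_screening <= 0 or self.n_diagnosed_screening <= 0:
            raise ValueError("both arms must have diagnosed cases")

    @property
    def pct_change(self) -> float:
        a, b = self.n_diagnosed_no_screening, self.n_diagnosed_screening
        return 100.0 * (b - a) / a

    @property
    def pct_overdiagnosis(self) -> float:
        a, b = self.n_diagnosed_no_screening, self.n_diagnosed_screening
        return 100.0 * (b - a) / b

    @property
    def pct_screen_detected(self) -> float:
        return 100.0 * self.n_screen_detected / self.n_diagnosed_screening

    @property
    def pct_interval(self) -> float:
        return 100.0 * self.n_interval / self.n_diagnosed_screening

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "scenario": self.scenario,
                "no_screening": self.n_diagnosed_no_screening,
                "screening": self.n_diagnosed_screening,
                "pct_change": self.pct_change,
                "pct_overdiagnosis": self.pct_overdiagnosis,
                "pct_screen_detected": self.pct_screen_detected,
                "pct_interval": self.pct_interval,
            }
        )


def _diagnosed_no_screening(histories, outcomes, followup_age):
    """Symptomatic-by-horizon cases in the eligible cohort (comparator arm)."""
    U = histories["sympt_age"].to_numpy(dtype=float)
    eligible = outcomes["eligible"].to_numpy(dtype=bool)
    return eligible & (U <= followup_age)


def summarize_program(
    histories: pd.DataFrame,
    outcomes: pd.DataFrame,
    followup_age: float,
    scenario: str = "",
) -> ProgramSummary:
    """Compare the paired no-screening and screening arms.

    The two arms share the same simulated natural histories (common random
    numbers): the no-screening arm diagnoses every eligible woman whose
    symptomatic age falls within the follow-up horizon, while the screening
    arm diagnoses screen-detected, interval and outside-program symptomatic
    cases.
    """
    mode = outcomes["mode"]
    n_no = int(_diagnosed_no_screening(histories, outcomes, followup_age).sum())
    n_scr = int(mode.isin(DIAGNOSED_MODES).sum())
    return ProgramSummary(
        scenario=scenario,
        n_diagnosed_no_screening=n_no,
        n_diagnosed_screening=n_scr,
        n_screen_detected=int((mode == "screen").sum()),
        n_interval=int((mode == "interval").sum()),
    )


def _band_counts(diameters: np.ndarray) -> np.ndarray:
    counts = np.array(
        [((diameters >= lo) & (diameters < hi)).sum() for lo, hi in SIZE_BANDS]
    )
    return counts


def size_distribution(
    histories: pd.DataFrame,
    outcomes: pd.DataFrame,
    followup_age: float,
    cap_mm: float | None = None,
) -> pd.DataFrame:
    """Tumor-size band distribution for both arms.

    No-screening diameters are the symptomatic diameters of comparator-arm
    cases; screening-arm diameters are the detection diameters of all
    diagnosed cases.  ``cap_mm`` truncates symptomatic diameters at a
    reporting maximum (it does not alter the model).
    """
    no_scr = _diagnosed_no_screening(histories, outcomes, followup_age)
    d_no = histories.loc[no_scr, "sympt_diameter"].to_numpy(dtype=float)
    diag = outcomes["mode"].isin(DIAGNOSED_MODES).to_numpy()
    d_scr = outcomes.loc[diag, "detection_diameter"].to_numpy(dtype=float)
    if cap_mm is not None:
        d_no = np.minimum(d_no, cap_mm)
        d_scr = np.minimum(d_scr, cap_mm)

    rows = []
    for arm, d in (("no_screening", d_no), ("screening", d_scr)):
        counts = _band_counts(d)
        for label, c in zip(SIZE_BAND_LABELS, counts):
            rows.append(
                {
                    "arm": arm,
                    "band": label,
                    "count": int(c),
                    "pct": 100.0 * c / len(d) if len(d) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _quantile_summary(x: np.ndarray) -> dict:
    # linear-interpolation quantiles (matches the small-sample convention
    # Q1 of {100,200,300} = 150)
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return {
        "n": len(x),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
    }


def doubling_time_summary(
    histories: pd.DataFrame,
    outcomes: pd.DataFrame,
    by_category: bool = True,
) -> pd.DataFrame:
    """Doubling-time (days) summaries per BMI category and detection mode."""
    dt = histories["doubling_time_days"].to_numpy(dtype=float)
    cats = histories["bmi_category"].astype(str).to_numpy()
    mode = outcomes["mode"].astype(str).to_numpy()
    rows = []
    groups = (
        [(c, m) for c in pd.unique(cats) for m in ("screen", "interval")]
        if by_category
        else [("all", m) for m in ("screen", "interval")]
    )
    for cat, m in groups:
        mask = (mode == m) if cat == "all" else ((cats == cat) & (mode == m))
        if not mask.any():
            continue
        rows.append({"bmi_category": cat, "mode": m, **_quantile_summary(dt[mask])})
    return pd.DataFrame(rows)


def presence_time_summary(
    histories: pd.DataFrame,
    outcomes: pd.DataFrame,
    by_category: bool = True,
) -> pd.DataFrame:
    """Sojourn-time (years, onset to symptoms) summaries for interval cancers."""
    up = histories["sojourn"].to_numpy(dtype=float)
    cats = histories["bmi_category"].astype(str).to_numpy()
    interval = (outcomes["mode"] == "interval").to_numpy()
    rows = []
    labels = list(pd.unique(cats)) if by_category else []
    for cat in ["all"] + labels:
        mask = interval if cat == "all" else (interval & (cats == cat))
        if not mask.any():
            continue
        rows.append({"bmi_category": cat, **_quantile_summary(up[mask])})
    return pd.DataFrame(rows)
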