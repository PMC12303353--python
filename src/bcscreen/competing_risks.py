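"""Competing-risks analysis of screening outcomes.

Screen detection (status 1) and interval detection (status 2) compete from
the date of tumor onset; women undetected by the end of screening are
censored (status 0).  The module encodes simulated outcomes as event
records, fits cause-specific Cox proportional-hazards models (competing
events censored at their event time), estimates Aalen-Johansen cumulative
incidence functions per BMI category, and tests for equality of CIFs across
categories with a Gray-type K-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "encode_events",
    "CoxFit",
    "fit_cause_specific_cox",
    "CifCurve",
    "estimate_cif",
    "cif_group_test",
]

CAUSE_STATUS = {"screen": 1, "interval": 2}


def encode_events(
    histories: pd.DataFrame,
    outcomes: pd.DataFrame,
    end_age: float = 65.0,
    max_detected_size_mm: float | None = None,
) -> pd.DataFrame:
    """Encode screening outcomes as competing-risks records.

    Follow-up runs from tumor onset; status 1 = screen-detected, 2 =
    interval-detected, 0 = censored at the end of screening (``end_age``).
    Only eligible women with tumor onset enter; symptomatic cases outside
    the program contribute censored records at their symptomatic age (they
    leave the screening risk set when diagnosed).  ``max_detected_size_mm``
    optionally drops detected records whose detection diameter exceeds the
    maximum (the program's reporting limit), censored records are kept.
    """
    mode = outcomes["mode"].astype(str).to_numpy()
    eligible = outcomes["eligible"].to_numpy(dtype=bool)
    onset = histories["onset_age"].to_numpy(dtype=float)
    det_age = outcomes["detection_age"].to_numpy(dtype=float)
    det_d = outcomes["detection_diameter"].to_numpy(dtype=float)

    status = np.zeros(len(histories), dtype=int)
    status[mode == "screen"] = 1
    status[mode == "interval"] = 2

    end_time = np.where(
        status > 0,
        det_age,
        np.where(mode == "symptomatic_outside_program", det_age, end_age),
    )
    time = end_time - onset

    keep = eligible & (time > 0)
    if max_detected_size_mm is not None:
        keep &= (status == 0) | (det_d <= max_detected_size_mm)

    df = pd.DataFrame(
        {
            "id": histories["id"].to_numpy()[keep],
            "time": time[keep],
            "status": status[keep],
            "bmi_category": histories["bmi_category"].astype(str).to_numpy()[keep],
            "age": end_time[keep],
        }
    )
    return df.reset_index(drop=True)


@dataclass
class CoxFit:
    """Cause-specific Cox fit: hazard ratios vs the underweight reference."""

    cause: str
    adjusted_for_age: bool
    coefficients: pd.Series
    hazard_ratios: pd.Series
    conf_int: pd.DataFrame          # columns: lower, upper (HR scale)
    n: int
    n_events: int
    ties_method: str = "efron"
    fitter: CoxPHFitter | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR lower 95%": self.conf_int["lower"],
                "HR upper 95%": self.conf_int["upper"],
            }
        )
        out.attrs["cause"] = self.cause
        out.attrs["n"] = self.n
        out.attrs["n_events"] = self.n_events
        return out


def fit_cause_specific_cox(
    records: pd.DataFrame,
    cause: str = "screen",
    adjust_for_age: bool = False,
    reference: str = "underweight",
) -> CoxFit:
    """Fit a cause-specific Cox model for one detection mode.

    Events of the competing cause are treated as censored at their event
    time (the cause-specific convention); BMI category enters as dummy
    variables against the ``reference`` level, optionally with age at
    detection/censoring as a second covariate.  Ties use the Efron
    approximation.
    """
    if cause not in CAUSE_STATUS:
        raise ValueError("cause must be 'screen' or 'interval'")
    cats = records["bmi_category"].astype(str)
    levels = [c for c in ("underweight", "normal", "overweight", "obese") if c in set(cats)]
    if len(levels) < 2:
        raise ValueError("need at least two BMI categories")
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from the data")

    target = CAUSE_STATUS[cause]
    df = pd.DataFrame(
        {
            "time": records["time"].to_numpy(dtype=float),
            "event": (records["status"].to_numpy() == target).astype(int),
        }
    )
    for lev in levels:
        if lev != reference:
            df[f"bmi_{lev}"] = (cats == lev).astype(float).to_numpy()
            if df[f"bmi_{lev}"].sum() == 0 or df.loc[df.event == 1, f"bmi_{lev}"].sum() == 0:
                raise ValueError(f"category {lev!r} has no events of cause {cause!r}")
    if adjust_for_age:
        df["age"] = records["age"].to_numpy(dtype=float)

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    ci = np.exp(cph.confidence_intervals_)
    ci.columns = ["lower", "upper"]
    return CoxFit(
        cause=cause,
        adjusted_for_age=adjust_for_age,
        coefficients=cph.params_,
        hazard_ratios=np.exp(cph.params_),
        conf_int=ci,
        n=len(df),
        n_events=int(df["event"].sum()),
        fitter=cph,
    )


@dataclass
class CifCurve:
    """Aalen-Johansen cumulative incidence step functions for one group."""

    group: str
    times: np.ndarray
    cif: dict            # cause label -> np.ndarray aligned with times
    survival: np.ndarray  # overall (all-cause) Kaplan-Meier S(t)

    def at(self, t: float, cause: str) -> float:
        """CIF value at time t (step function, right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.cif[cause][idx]) if idx >= 0 else 0.0

    def plot(self, ax=None):
        """Step plot of both cause-specific CIFs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cause, values in self.cif.items():
            ax.step(self.times, values, where="post", label=f"{self.group}: {cause}")
        ax.set_xlabel("years since tumor onset")
        ax.set_ylabel("cumulative incidence")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def _aalen_johansen(time, status, causes=(1, 2)):
    """Vectorized Aalen-Johansen estimator with exact tie handling.

    CIF_k(t) = sum_{s<=t} S(s-) dN_k(s) / Y(s), with S the all-cause
    Kaplan-Meier estimate; satisfies sum_k CIF_k(t) + S(t) = 1 at every
    event time when there is no censoring before t.
    """
    order = np.argsort(time, kind="stable")
    time = np.asarray(time, float)[order]
    status = np.asarray(status)[order]
    ut, inv = np.unique(time, return_inverse=True)
    m = len(ut)
    n = len(time)
    # at-risk counts just before each unique time
    counts = np.bincount(inv, minlength=m)
    at_risk = n - np.concatenate([[0], np.cumsum(counts)[:-1]])
    d_all = np.bincount(inv, weights=(status > 0).astype(float), minlength=m)
    with np.errstate(invalid="ignore"):
        S = np.cumprod(1.0 - d_all / at_risk)
    S_minus = np.concatenate([[1.0], S[:-1]])
    cifs = {}
    for k in causes:
        d_k = np.bincount(inv, weights=(status == k).astype(float), minlength=m)
        cifs[k] = np.cumsum(S_minus * d_k / at_risk)
    return ut, cifs, S


def estimate_cif(records: pd.DataFrame, by: str = "bmi_category") -> dict[str, CifCurve]:
    """Aalen-Johansen CIF per group for both causes."""
    out = {}
    for group, d in records.groupby(by, observed=True):
        ut, cifs, S = _aalen_johansen(d["time"].to_numpy(), d["status"].to_numpy())
        out[str(group)] = CifCurve(
            group=str(group),
            times=ut,
            cif={"screen": cifs[1], "interval": cifs[2]},
            survival=S,
        )
    return out


def _censoring_survival(time, status):
    """Kaplan-Meier of the censoring distribution (status 0 as the event)."""
    ut, cifs, S = _aalen_johansen(time, np.where(status == 0, 1, 0), causes=(1,))
    return ut, S


def cif_group_test(
    records: pd.DataFrame,
    cause: str = "screen",
    by: str = "bmi_category",
) -> tuple[float, int, float]:
    """Gray-type K-sample test for equality of CIFs across groups.

    Score test on the subdistribution hazard (rho = 0): subjects who fail
    from the competing cause remain in the subdistribution risk set with an
    inverse-probability-of-censoring weight G(t-)/G(T_i), G estimated by the
    pooled censoring Kaplan-Meier.  The statistic compares observed and
    expected cause-specific events per group over the weighted risk sets,
    with a hypergeometric-type working variance; identical groups give a
    statistic of exactly zero.  Returns (chi2, df, p).
    """
    if cause not in CAUSE_STATUS:
        raise ValueError("cause must be 'screen' or 'interval'")
    target = CAUSE_STATUS[cause]
    groups = np.asarray(records[by].astype(str))
    labels = pd.unique(groups)
    K = len(labels)
    if K < 2:
        raise ValueError("need at least two groups")

    time = records["time"].to_numpy(dtype=float)
    status = records["status"].to_numpy()
    n = len(time)

    ct, G = _censoring_survival(time, status)
    G_minus = np.concatenate([[1.0], G[:-1]])

    def G_at_minus(t):
        # G(t-): left-continuous censoring survival
        idx = np.searchsorted(ct, t, side="left")
        return np.where(idx == 0, 1.0, G[np.maximum(idx - 1, 0)])

    lab_order = {lab: i for i, lab in enumerate(labels)}
    gidx = np.array([lab_order[g] for g in groups])

    # all-time grid: unique observed times, with risk sets evaluated just
    # before each.  Subjects with T_i >= s contribute 1 to their group's
    # risk set; competing failures with T_i < s stay in it with weight
    # G(s-)/G(T_i-).
    ut, inv = np.unique(time, return_inverse=True)
    m = len(ut)
    Gm_ut = G_at_minus(ut)
    G_own = G_at_minus(time)

    onehot = np.zeros((m, K))
    np.add.at(onehot, (inv, gidx), 1.0)
    left_cum = np.concatenate([np.zeros((1, K)), np.cumsum(onehot, axis=0)[:-1]])
    still_at_risk = onehot.sum(axis=0) - left_cum  # (m, K): # with T_i >= ut

    is_comp = status == (3 - target)
    comp_w = np.zeros((m, K))
    np.add.at(
        comp_w,
        (inv[is_comp], gidx[is_comp]),
        1.0 / np.maximum(G_own[is_comp], 1e-300),
    )
    comp_cum = np.concatenate([np.zeros((1, K)), np.cumsum(comp_w, axis=0)[:-1]])

    Y = still_at_risk + Gm_ut[:, None] * comp_cum  # (m, K)
    Ytot = Y.sum(axis=1)

    dNk = np.zeros((m, K))
    is_ev = status == target
    np.add.at(dNk, (inv[is_ev], gidx[is_ev]), 1.0)
    dN = dNk.sum(axis=1)

    use = (dN > 0) & (Ytot > 0)
    p = Y[use] / Ytot[use][:, None]
    dN_use = dN[use]

    O = dNk[use].sum(axis=0)
    E = (p * dN_use[:, None]).sum(axis=0)
    V = np.einsum("s,sj,sk->jk", dN_use, p, -p)
    V[np.diag_indices(K)] += (dN_use[:, None] * p).sum(axis=0)

    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    df = K - 1
    p_value = float(stats.chi2.sf(chi2, df))
    return chi2, df, p_value
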