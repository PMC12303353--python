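"""Full study scenarios: the canned simulation designs behind the headline
results (program shares, pooled tumor characteristics, and the pooled
competing-risks analysis), each recomputed from scratch by running the
package at full scale.

Every function takes a single integer seed and derives per-run seeds from a
``SeedSequence``, so the whole study is replayable from one number.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .competing_risks import encode_events, estimate_cif, fit_cause_specific_cox
from .config import AnalysisConfig
from .natural_history import NaturalHistoryModel, simulate_life_histories
from .outcomes import ProgramSummary, size_distribution, summarize_program
from .population import BMI_SCENARIOS, CohortSpec, generate_population
from .screening import (
    SENSITIVITY_PROFILES,
    ScreeningPolicy,
    ScreeningProgram,
    run_screening,
)

__all__ = [
    "printed_table_identities",
    "biennial_normal_shares",
    "pooled_normal_weight_doubling_times",
    "pooled_tumor_characteristics",
    "stratified_biennial_small_size_share",
    "pooled_competing_risks",
]

FOLLOWUP_AGE = 65.0
CATEGORY_SCENARIOS = ("underweight", "normal", "overweight", "obese")


def printed_table_identities(
    n_no_screening: int = 20460, n_screening: int = 22284
) -> dict[str, float]:
    """% change and % overdiagnosis from a pair of diagnosed counts.

    Defaults are the annual/moderate program's published counts; the two
    percentages are exact arithmetic identities of the pair.
    """
    s = ProgramSummary("printed", n_no_screening, n_screening, 0, 0)
    return {"pct_change": s.pct_change, "pct_overdiagnosis": s.pct_overdiagnosis}


def _simulate_histories(scenario_label, seed, births=5000):
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_nh, rng_scr = (np.random.default_rng(s) for s in ss.spawn(3))
    pop = generate_population(
        CohortSpec(1986, 2020, births), BMI_SCENARIOS[scenario_label], rng_pop
    )
    model = NaturalHistoryModel()
    hist = simulate_life_histories(pop, model, rng_nh)
    return hist, model, rng_scr


def _program(interval_months, stratified=False):
    by_cat = {"obese": SENSITIVITY_PROFILES["high"]} if stratified else {}
    return ScreeningProgram(
        policy=ScreeningPolicy(30, 65, interval_months),
        sensitivity=SENSITIVITY_PROFILES["moderate"],
        sensitivity_by_category=by_cat,
    )


def biennial_normal_shares(seed: int, births: int = 5000) -> dict[str, float]:
    """Screen-detected and interval shares, biennial normal-weight program."""
    hist, model, rng = _simulate_histories("normal", seed, births)
    out = run_screening(hist, _program(24), model, rng, followup_age=FOLLOWUP_AGE)
    s = summarize_program(hist, out, FOLLOWUP_AGE, scenario="normal")
    return {
        "pct_screen_detected": s.pct_screen_detected,
        "pct_interval": s.pct_interval,
        "n_diagnosed_screening": s.n_diagnosed_screening,
        "pct_change": s.pct_change,
        "pct_overdiagnosis": s.pct_overdiagnosis,
    }


def _pooled_outcomes(scenarios, intervals, seed, births, stratified=False):
    """Pool (histories, outcomes) across scenarios x interval strategies.

    Strategies share each scenario's natural histories (common random
    numbers); scenarios are independent replicates.
    """
    hists, outs = [], []
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(scenarios))
    for scen, s in zip(scenarios, seeds):
        hist, model, rng = _simulate_histories(scen, s.entropy % (2**31), births)
        for months in intervals:
            out = run_screening(
                hist, _program(months, stratified), model,
                np.random.default_rng(rng.integers(2**31)),
                followup_age=FOLLOWUP_AGE,
            )
            hists.append(hist)
            outs.append(out)
    return pd.concat(hists, ignore_index=True), pd.concat(outs, ignore_index=True)


def pooled_normal_weight_doubling_times(seed: int, births: int = 5000) -> dict[str, float]:
    """Median doubling times (days) by detection mode, normal-weight stratum,
    pooled over the annual/biennial/triennial strategies."""
    hist, out = _pooled_outcomes(["normal"], (12, 24, 36), seed, births)
    normal = hist["bmi_category"].astype(str).to_numpy() == "normal"
    dt = hist["doubling_time_days"].to_numpy()
    mode = out["mode"].astype(str).to_numpy()
    return {
        "median_dt_screen": float(np.median(dt[normal & (mode == "screen")])),
        "median_dt_interval": float(np.median(dt[normal & (mode == "interval")])),
    }


def pooled_tumor_characteristics(seed: int, births: int = 5000) -> dict[str, float]:
    """Pooled-over-BMI-scenarios medians: detection sizes and presence time."""
    hist, out = _pooled_outcomes(CATEGORY_SCENARIOS, (12, 24, 36), seed, births)
    mode = out["mode"].astype(str).to_numpy()
    d = out["detection_diameter"].to_numpy()
    sojourn = hist["sojourn"].to_numpy()
    interval = mode == "interval"
    return {
        "median_size_screen": float(np.median(d[mode == "screen"])),
        "median_size_interval": float(np.median(np.minimum(d[interval], 120.0))),
        "median_presence_interval": float(np.median(sojourn[interval])),
    }


def stratified_biennial_small_size_share(seed: int, births: int = 5000) -> dict[str, float]:
    """Share of screening-arm diagnoses below 10 mm under the BMI risk-based
    biennial program (high sensitivity for obese women, general population)."""
    hist, model, rng = _simulate_histories("general", seed, births)
    out = run_screening(
        hist, _program(24, stratified=True), model, rng, followup_age=FOLLOWUP_AGE
    )
    tab = size_distribution(hist, out, FOLLOWUP_AGE, cap_mm=None)
    row = tab[(tab.arm == "screening") & (tab.band == "0-9 mm")]
    return {"pct_size_0_9": float(row["pct"].iloc[0])}


def pooled_competing_risks(
    seed: int, n_replicates: int = 10, births: int = 5000
) -> dict[str, float]:
    """Pooled general-population event records: CIF at 50 years and the
    age-adjusted cause-specific hazard ratio for screen detection.

    The whole screening-data analysis assumes a maximum detected tumor size
    of 50 mm, so detected records above it are dropped before both the CIF
    estimation and the Cox fit (censored records are kept).
    """
    ss = np.random.SeedSequence(seed)
    all_filtered = []
    for child in ss.spawn(n_replicates):
        rep_seed = child.entropy % (2**31)
        hist, model, rng = _simulate_histories("general", rep_seed, births)
        out = run_screening(
            hist, _program(24, stratified=True), model, rng, followup_age=FOLLOWUP_AGE
        )
        all_filtered.append(
            encode_events(hist, out, end_age=FOLLOWUP_AGE, max_detected_size_mm=50.0)
        )
    filtered = pd.concat(all_filtered, ignore_index=True)

    cif = estimate_cif(filtered)["normal"]
    fit = fit_cause_specific_cox(filtered, cause="screen", adjust_for_age=True)
    return {
        "cif_screen_50y_normal": cif.at(50.0, "screen"),
        "hr_screen_normal_age_adjusted": float(fit.hazard_ratios["bmi_normal"]),
        "n_records": int(len(filtered)),
    }
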