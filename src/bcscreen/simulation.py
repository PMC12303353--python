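"""Scenario orchestration: paired no-screening / screening simulation.

``ScreeningSimulation`` is the model object (built from a ``RunConfig``);
``run()`` executes population generation, natural history, the screening
overlay and the analysis encodings with common random numbers across the
paired arms, and returns a ``SimulationResults`` carrying the per-woman
tables and the aggregate summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import outcomes as outcomes_mod
from .competing_risks import encode_events
from .config import RunConfig
from .natural_history import simulate_life_histories
from .population import generate_population
from .screening import run_screening

__all__ = ["ScreeningSimulation", "SimulationResults", "sensitivity_sweep"]

logger = logging.getLogger("bcscreen")


@dataclass
class SimulationResults:
    """Results of one paired scenario run."""

    config: RunConfig
    histories: pd.DataFrame
    outcomes: pd.DataFrame
    program_summary: outcomes_mod.ProgramSummary
    size_distribution: pd.DataFrame
    doubling_time: pd.DataFrame
    presence_time: pd.DataFrame
    events: pd.DataFrame

    def summary(self) -> pd.Series:
        """Headline program-comparison numbers."""
        return self.program_summary.as_series()

    def plot_size_distribution(self, ax=None):
        """Grouped bar chart of the size-band shares in both arms."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        piv = self.size_distribution.pivot(index="band", columns="arm", values="pct")
        piv.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("% of diagnosed cases")
        ax.set_xlabel("tumor size at detection")
        return ax

    def export(self, directory) -> None:
        """Write all tables (CSV) and the manifest (JSON) to a directory."""
        from pathlib import Path

        from .config import save_manifest

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cols = [
            "id", "birth_year", "bmi", "bmi_category", "onset_age",
            "growth_rate", "doubling_time_days", "sympt_age", "sympt_diameter",
        ]
        self.histories[cols].to_csv(d / "life_histories.csv", index=False)
        self.outcomes.to_csv(d / "detection_outcomes.csv", index=False)
        self.program_summary.as_series().to_frame().T.to_csv(d / "program_summary.csv", index=False)
        self.size_distribution.to_csv(d / "size_distribution.csv", index=False)
        self.doubling_time.to_csv(d / "doubling_time.csv", index=False)
        self.presence_time.to_csv(d / "presence_time.csv", index=False)
        self.events.to_csv(d / "event_records.csv", index=False)
        save_manifest(self.config, d / "manifest.json")


class ScreeningSimulation:
    """Paired no-screening / screening microsimulation for one scenario."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()

    def run(self, seed: int | None = None) -> SimulationResults:
        """Execute the scenario; ``seed`` overrides the configured seed.

        One global seed drives a hierarchical ``SeedSequence``, so every
        stage's randomness is reproducible, and the screening arm reuses
        the no-screening natural histories (common random numbers).
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        ss = np.random.SeedSequence(cfg.seed)
        rng_pop, rng_nh, rng_scr = (np.random.default_rng(s) for s in ss.spawn(3))

        pop = generate_population(cfg.cohorts, cfg.scenario, rng_pop)
        logger.info("population: %d women (%s)", len(pop), cfg.scenario.label)

        hist = simulate_life_histories(pop, cfg.model, rng_nh)
        n_onset = int(hist["onset_age"].notna().sum())
        logger.info("onsets: %d (%.2f%%)", n_onset, 100 * n_onset / len(hist))

        out = run_screening(
            hist,
            cfg.program,
            cfg.model,
            rng_scr,
            followup_age=cfg.analysis.followup_age,
            cohort=cfg.analysis.cohort,
            interval_requires_tumor_present=cfg.analysis.interval_requires_tumor_present,
        )
        counts = out["mode"].value_counts().to_dict()
        logger.info("detection modes: %s", counts)

        summary = outcomes_mod.summarize_program(
            hist, out, cfg.analysis.followup_age, scenario=cfg.scenario.label
        )
        sizes = outcomes_mod.size_distribution(
            hist, out, cfg.analysis.followup_age, cap_mm=cfg.analysis.interval_size_cap_mm
        )
        dts = outcomes_mod.doubling_time_summary(hist, out)
        presence = outcomes_mod.presence_time_summary(hist, out)
        events = encode_events(
            hist, out, end_age=cfg.program.policy.end_age, max_detected_size_mm=None
        )
        return SimulationResults(
            config=cfg,
            histories=hist,
            outcomes=out,
            program_summary=summary,
            size_distribution=sizes,
            doubling_time=dts,
            presence_time=presence,
            events=events,
        )


def _perturbed_configs(config: RunConfig, targets, perturbation):
    yield "baseline", config
    for direction in (+1, -1):
        f = 1.0 + direction * perturbation
        if "onset" in targets:
            onset = replace(
                config.model.onset,
                A=config.model.onset.A * f,
                B=config.model.onset.B * f,
                delta=config.model.onset.delta * f,
            )
            yield f"onset{'+' if direction > 0 else '-'}{perturbation:.0%}", replace(
                config, model=replace(config.model, onset=onset)
            )
        if "sensitivity" in targets:
            sens = replace(
                config.program.sensitivity,
                beta0=config.program.sensitivity.beta0 * f,
                beta1=config.program.sensitivity.beta1 * f,
            )
            yield f"sensitivity{'+' if direction > 0 else '-'}{perturbation:.0%}", replace(
                config, program=replace(config.program, sensitivity=sens)
            )


def sensitivity_sweep(
    config: RunConfig,
    targets=("onset",),
    perturbation: float = 0.10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rerun the scenario with targeted parameters scaled by (1 +/- p).

    ``targets`` selects parameter groups: ``onset`` perturbs (A, B, delta),
    ``sensitivity`` perturbs (beta0, beta1).  Returns a table of
    program-comparison outcomes side by side, one row per perturbed run,
    with the perturbed parameter values recorded.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be non-negative")
    rows = []
    for label, cfg in _perturbed_configs(config, targets, perturbation):
        res = ScreeningSimulation(cfg).run(seed=seed)
        row = res.summary()
        row["run"] = label
        row["onset_params"] = (cfg.model.onset.A, cfg.model.onset.B, cfg.model.onset.delta)
        row["sensitivity_params"] = (
            cfg.program.sensitivity.beta0,
            cfg.program.sensitivity.beta1,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("run")
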