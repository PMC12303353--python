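"""Run configuration: YAML/JSON-backed settings with model defaults.

Any omitted block falls back to the published simulation parameters (onset
A, B, delta and the 0.48 age scaling; growth lambda0, lambda1, phi;
symptomatic hazard eta; sensitivity profiles; the 30-65 screening window
and the 0.8@0.90 / 0.2@0.15 attendance mixture).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .natural_history import (
    GrowthModel,
    NaturalHistoryModel,
    OnsetModel,
    SymptomaticModel,
    TumorGeometry,
)
from .population import BMI_SCENARIOS, BmiScenario, CohortSpec
from .screening import (
    SENSITIVITY_PROFILES,
    AttendanceModel,
    ScreeningPolicy,
    ScreeningProgram,
    SensitivityModel,
)

__all__ = ["AnalysisConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage settings."""

    followup_age: float = 65.0
    cohort: str = "onset_in_program"
    interval_requires_tumor_present: bool = False
    max_detected_size_mm: float = 50.0   # event-record filter for Cox fits
    interval_size_cap_mm: float = 120.0  # reporting cap for symptomatic sizes


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration for one paired simulation scenario."""

    cohorts: CohortSpec = field(default_factory=CohortSpec)
    scenario: BmiScenario = field(default_factory=lambda: BMI_SCENARIOS["general"])
    model: NaturalHistoryModel = field(default_factory=NaturalHistoryModel)
    program: ScreeningProgram = field(default_factory=ScreeningProgram)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "bcscreen-output"

    def manifest(self) -> dict:
        """JSON-serializable record sufficient to re-execute the run."""
        return {
            "seed": self.seed,
            "cohorts": vars(self.cohorts).copy(),
            "scenario": vars(self.scenario).copy(),
            "onset": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self.model.onset).items()},
            "growth": vars(self.model.growth).copy(),
            "geometry": vars(self.model.geometry).copy(),
            "symptomatic": vars(self.model.symptomatic).copy(),
            "policy": vars(self.program.policy).copy(),
            "attendance": {
                "mode": self.program.attendance.mode,
                "groups": [list(g) for g in self.program.attendance.groups],
            },
            "sensitivity": vars(self.program.sensitivity).copy(),
            "sensitivity_by_category": {
                k: vars(v).copy() for k, v in self.program.sensitivity_by_category.items()
            },
            "analysis": vars(self.analysis).copy(),
        }


def _build_scenario(block) -> BmiScenario:
    if isinstance(block, str):
        return BMI_SCENARIOS[block]
    label = block.get("label", "custom")
    if "mean" not in block and label in BMI_SCENARIOS:
        return BMI_SCENARIOS[label]
    base = {"lower_bound": 10.0, "upper_bound": 80.0}
    base.update({k: v for k, v in block.items() if k != "label"})
    return BmiScenario(label=label, **base)


def _build_sensitivity(block) -> SensitivityModel:
    if isinstance(block, str):
        return SENSITIVITY_PROFILES[block]
    if "profile" in block:
        return SENSITIVITY_PROFILES[block["profile"]]
    return SensitivityModel(**block)


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file path or a plain dict."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)
    else:
        data = dict(source)
    data = data or {}

    cohorts = CohortSpec(**data.get("population", {}).get("cohorts", {}))
    scenario = _build_scenario(data.get("population", {}).get("bmi", "general"))

    mblock = data.get("model", {})
    onset_kwargs = dict(mblock.get("onset", {}))
    if "grid" in onset_kwargs:
        onset_kwargs["grid"] = tuple(onset_kwargs["grid"])
    model = NaturalHistoryModel(
        onset=OnsetModel(**onset_kwargs),
        growth=GrowthModel(**mblock.get("growth", {})),
        geometry=TumorGeometry(**mblock.get("geometry", {})),
        symptomatic=SymptomaticModel(**mblock.get("symptomatic", {})),
    )

    sblock = data.get("screening", {})
    att = sblock.get("attendance", {})
    if isinstance(att, str):
        attendance = AttendanceModel(mode=att)
    else:
        att = dict(att)
        if "groups" in att:
            att["groups"] = tuple(tuple(g) for g in att["groups"])
        attendance = AttendanceModel(**att)
    by_cat = {
        k: _build_sensitivity(v)
        for k, v in sblock.get("sensitivity_by_category", {}).items()
    }
    program = ScreeningProgram(
        policy=ScreeningPolicy(**sblock.get("policy", {})),
        attendance=attendance,
        sensitivity=_build_sensitivity(sblock.get("sensitivity", "moderate")),
        sensitivity_by_category=by_cat,
    )

    analysis = AnalysisConfig(**data.get("analysis", {}))
    return RunConfig(
        cohorts=cohorts,
        scenario=scenario,
        model=model,
        program=program,
        analysis=analysis,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "bcscreen-output")),
    )


def save_manifest(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config.manifest(), indent=2, default=str))
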