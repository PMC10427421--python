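"""Bundled default reward tables and thresholds.

These are synthetic consensus-style defaults authored for this package: they
encode the design philosophy that missing a melanoma is penalized far more
heavily than excising a benign lesion, that short-term monitoring of an early
melanoma carries only a moderate penalty, and that local therapy is rewarded
for actinic keratosis.  They are editable configuration, not elicited expert
data — replace them with your own experts' tables via the same CSV/JSON
formats.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import RewardTable, ScenarioSpec, SCENARIOS, ThresholdSpec, load_reward_table

__all__ = ["default_reward_table", "default_thresholds", "data_path"]

_FILES = {
    "diagnosisRL": "reward_diagnosis_synthetic.csv",
    "binary": "reward_binary_synthetic.csv",
    "multiclass_therapy": "reward_multiclass_synthetic.csv",
    "patient_centered": "reward_patient_synthetic.csv",
}


def data_path(name: str) -> Path:
    return Path(resources.files("dermrl") / "data" / name)


def default_reward_table(scenario: str | ScenarioSpec) -> RewardTable:
    name = scenario.name if isinstance(scenario, ScenarioSpec) else scenario
    table = load_reward_table(data_path(_FILES[name]),
                              expected_columns=SCENARIOS[name].action_set)
    return table


def default_thresholds() -> ThresholdSpec:
    return ThresholdSpec.from_json(data_path("thresholds_synthetic.json"))
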