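"""Baseline and oracle decision policies.

Three non-learning policies against which the Q-learning layer is compared:

* the naive policy, which picks the top-1 predicted diagnosis and applies its
  optimal management;
* the threshold hierarchy, which escalates management through ordered
  probability cut-offs (melanoma, then overall malignancy, then BCC, then
  AKIEC, then — in the patient scenario — a monitoring cut-off);
* the Bayes policy, which maximizes expected reward under the classifier's
  probabilities and is the analytic oracle for a converged Q-policy on
  calibrated inputs.

All threshold comparisons are strict (a probability must *exceed* its cut-off
to trigger the rule), and expected-reward ties resolve toward the more cautious
action (higher safety rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (BENIGN, CLASS_ORDER, MALIGNANT, DiagnosisLabel, ManagementAction,
                   RewardTable, RewardTableError, ScenarioSpec, ThresholdSpec,
                   malignancy_probability, optimal_management, validate_distribution)
from .records import ClassifierState, LesionRecord

__all__ = ["PolicyDecision", "naive_policy", "threshold_policy", "bayes_policy",
           "expected_rewards", "collapse_binary_rewards", "binary_reward_threshold",
           "run_policy_batch"]


@dataclass(frozen=True)
class PolicyDecision:
    lesion_id: str
    action: object                       # ManagementAction or DiagnosisLabel
    policy_name: str
    diagnosis_call: DiagnosisLabel | None = None
    auxiliary: float | None = None       # probability used at the decisive rule


def naive_policy(s: ClassifierState, scenario: ScenarioSpec,
                 lesion_id: str = "") -> PolicyDecision:
    """Optimal management for the top-1 predicted class (ties to lower class index)."""
    p = validate_distribution(s.probabilities)
    call = CLASS_ORDER[int(np.argmax(p))]
    action = call if not scenario.is_management else optimal_management(call, scenario)
    return PolicyDecision(lesion_id, action, "naive", call, float(p.max()))


def threshold_policy(s: ClassifierState, t: ThresholdSpec, scenario: ScenarioSpec,
                     lesion_id: str = "") -> PolicyDecision:
    """Preference-based threshold hierarchy.

    Rules are consulted in order and the first exceeded cut-off decides:
    (1) p[MEL] > melanoma_excise -> EXCISE; (2) overall malignancy >
    malignancy_excise -> EXCISE; (3) p[BCC] > bcc_excise -> EXCISE;
    (4) p[AKIEC] > akiec_local -> local therapy if the scenario offers it,
    else EXCISE; (5) patient scenario: malignancy > monitor -> MONITOR;
    otherwise the fallback action (dismiss).  A rule whose cut-off is left
    undefined is skipped; rule 5 requires its cut-off in the patient scenario.
    """
    if not scenario.is_management:
        raise ValueError("threshold policy applies to management scenarios only")
    p = validate_distribution(s.probabilities)
    p_mal = malignancy_probability(p)
    name = "threshold"

    def dec(action, prob):
        return PolicyDecision(lesion_id, action, name, None, float(prob))

    p_mel = p[DiagnosisLabel.MEL.index]
    if t.melanoma_excise is not None and p_mel > t.melanoma_excise:
        return dec(ManagementAction.EXCISE, p_mel)
    if t.malignancy_excise is not None and p_mal > t.malignancy_excise:
        return dec(ManagementAction.EXCISE, p_mal)
    p_bcc = p[DiagnosisLabel.BCC.index]
    if t.bcc_excise is not None and p_bcc > t.bcc_excise:
        return dec(ManagementAction.EXCISE, p_bcc)
    p_ak = p[DiagnosisLabel.AKIEC.index]
    if t.akiec_local is not None and p_ak > t.akiec_local:
        act = (ManagementAction.TREAT_LOCALLY
               if ManagementAction.TREAT_LOCALLY in scenario.action_set
               else ManagementAction.EXCISE)
        return dec(act, p_ak)
    if ManagementAction.MONITOR in scenario.action_set:
        if t.monitor is None:
            raise ValueError("patient scenario consulted the monitor rule but no "
                             "monitor threshold is configured")
        if p_mal > t.monitor:
            return dec(ManagementAction.MONITOR, p_mal)
    return dec(t.fallback_action, p_mal)


def _tie_key(col) -> float:
    # prefer cautious management actions; prefer lower canonical index diagnoses
    if isinstance(col, ManagementAction):
        return col.safety_rank
    return -col.index


def expected_rewards(p: np.ndarray, rewards: RewardTable) -> np.ndarray:
    """E[reward | action] = sum_d p[d] * R[d, action], for each column."""
    p = validate_distribution(p)
    return p @ rewards.values


def bayes_policy(p: np.ndarray, rewards: RewardTable,
                 lesion_id: str = "") -> PolicyDecision:
    """Expected-reward maximizing action under the predictive distribution."""
    er = expected_rewards(p, rewards)
    best = np.flatnonzero(er == er.max())  # exact ties only
    cols = [rewards.col_labels[i] for i in best]
    action = max(cols, key=_tie_key)
    call = action if isinstance(action, DiagnosisLabel) else None
    return PolicyDecision(lesion_id, action, "bayes", call, float(er.max()))


def collapse_binary_rewards(rewards: RewardTable,
                            class_priors: np.ndarray) -> np.ndarray:
    """Prior-weighted collapse of a 7x2 dismiss/excise table to a 2x2 one.

    Returns a (2, 2) array indexed [malignant/benign, DISMISS/EXCISE], each row
    the prior-weighted average reward within that partition.
    """
    want = {ManagementAction.DISMISS, ManagementAction.EXCISE}
    if set(rewards.col_labels) != want:
        raise RewardTableError("binary collapse needs exactly DISMISS and EXCISE columns")
    j_dis = rewards.col_labels.index(ManagementAction.DISMISS)
    j_exc = rewards.col_labels.index(ManagementAction.EXCISE)
    pr = np.asarray(class_priors, dtype=float)
    out = np.zeros((2, 2))
    for row, part in enumerate((MALIGNANT, BENIGN)):
        idx = [d.index for d in CLASS_ORDER if d in part]
        w = pr[idx] / pr[idx].sum()
        out[row, 0] = w @ rewards.values[idx, j_dis]
        out[row, 1] = w @ rewards.values[idx, j_exc]
    return out


def binary_reward_threshold(collapsed: np.ndarray) -> float:
    """Malignancy probability above which the Bayes policy excises.

    For a 2x2 table R[{mal, ben}, {DISMISS, EXCISE}] the expected rewards of the
    two actions cross at

        p* = (R[ben,DIS] - R[ben,EXC]) /
             (R[mal,EXC] - R[mal,DIS] + R[ben,DIS] - R[ben,EXC])

    and excision is optimal iff p_mal >= p*.  Raises for tables where excision
    never becomes preferable as malignancy probability rises (denominator <= 0).
    """
    R = np.asarray(collapsed, dtype=float)
    if R.shape != (2, 2):
        raise ValueError("collapsed table must be 2x2")
    num = R[1, 0] - R[1, 1]
    den = R[0, 1] - R[0, 0] + R[1, 0] - R[1, 1]
    if den <= 0:
        raise ValueError("degenerate reward table: expected rewards never cross")
    return float(num / den)


def run_policy_batch(records: Sequence[LesionRecord], scenario: ScenarioSpec,
                     *, thresholds: ThresholdSpec | None = None,
                     rewards: RewardTable | None = None,
                     policy: str = "naive") -> list[PolicyDecision]:
    """Apply one named policy to every record; see :func:`decisions_to_frame`."""
    out = []
    for r in records:
        if policy == "naive":
            out.append(naive_policy(r.state, scenario, r.lesion_id))
        elif policy == "threshold":
            assert thresholds is not None, "threshold policy needs a ThresholdSpec"
            out.append(threshold_policy(r.state, thresholds, scenario, r.lesion_id))
        elif policy == "bayes":
            assert rewards is not None, "bayes policy needs a RewardTable"
            out.append(bayes_policy(r.state.probabilities, rewards, r.lesion_id))
        else:
            raise ValueError(f"unknown policy {policy!r}")
    return out


def decisions_to_frame(decisions: Sequence[PolicyDecision]) -> pd.DataFrame:
    df = pd.DataFrame([
        {"lesion_id": d.lesion_id, "policy": d.policy_name,
         "diagnosis_call": d.diagnosis_call.value if d.diagnosis_call else "",
         "action": d.action.value,
         "auxiliary": np.nan if d.auxiliary is None else d.auxiliary}
        for d in decisions])
    return df.astype({"auxiliary": float})
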