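"""Scenario orchestration: simulator → training → policies → evaluation.

A :class:`RunConfig` plus a single global seed reproduces a full experiment:
the seed fans out to named substreams (data, training, evaluation) via
``numpy.random.SeedSequence`` so each stage can be re-run in isolation.  Every
output artifact embeds the config hash, the seed and the class-order
fingerprint.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (CLASS_CODES, CLASS_ORDER, MALIGNANT, DiagnosisLabel,
                   ManagementAction, RewardTable, ScenarioSpec, SCENARIOS,
                   ThresholdSpec, load_reward_table, malignancy_probability)
from .defaults import default_reward_table, default_thresholds
from .metrics import (accuracy, average_recall, class_sensitivity, confusion,
                      entropy_comparison, patient_metrics, proportion_ci,
                      roc_and_operating_points)
from .policies import PolicyDecision, decisions_to_frame, run_policy_batch
from .qlearn import (TrainConfig, TrainedPolicy, normalize_patient_states,
                     order_episode, state_matrix, train_q)
from .records import LesionRecord, PatientCohort, records_to_frame
from .synth import (CohortConfig, GeneratorConfig, ISIC_TEST_COUNTS,
                    make_isic_fixture, sample_cohort, sample_states)

__all__ = ["RunConfig", "run_scenario", "run_patient_cv", "rl_decisions"]

log = logging.getLogger("dermrl")

_ISIC_PRIORS = tuple(np.array([ISIC_TEST_COUNTS[d] for d in CLASS_ORDER], float)
                     / sum(ISIC_TEST_COUNTS.values()))


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one scenario run."""

    scenario: str = "diagnosisRL"
    seed: int = 0
    n_train: int = 10_000
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    reward_table_path: str | None = None       # None -> bundled default
    thresholds_path: str | None = None
    aggregation: str = "median"
    train: TrainConfig = field(default_factory=TrainConfig)
    sl_temperature: float | None = None        # distort displayed SL probabilities
    output_dir: str | None = None

    def resolve_rewards(self) -> RewardTable:
        scen = SCENARIOS[self.scenario]
        if self.reward_table_path:
            return load_reward_table(self.reward_table_path,
                                     expected_columns=scen.action_set)
        return default_reward_table(self.scenario)

    def resolve_thresholds(self) -> ThresholdSpec:
        if self.thresholds_path:
            return ThresholdSpec.from_json(self.thresholds_path)
        return default_thresholds()

    def fingerprint(self) -> dict:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return {"config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
                "seed": self.seed, "class_order": list(CLASS_CODES)}


def _substream_seeds(seed: int, n: int = 4) -> list[int]:
    # independent named substreams, each below 2**31
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def rl_decisions(policy: TrainedPolicy, data: Sequence[LesionRecord] | PatientCohort,
                 scenario: ScenarioSpec) -> list[PolicyDecision]:
    """Greedy policy readout over a lesion list or a patient cohort."""
    out: list[PolicyDecision] = []
    if isinstance(data, PatientCohort):
        for pid, lesions in data.patients:
            ordered = order_episode(list(lesions))
            X, _ = state_matrix(ordered)
            X = normalize_patient_states(X)
            for rec, a in zip(ordered, policy.greedy_actions_batch(X)):
                out.append(PolicyDecision(rec.lesion_id, scenario.action_set[a], "rl"))
    else:
        X, _ = state_matrix(list(data))
        for rec, a in zip(data, policy.greedy_actions_batch(X)):
            act = scenario.action_set[a]
            call = act if isinstance(act, DiagnosisLabel) else None
            out.append(PolicyDecision(rec.lesion_id, act, "rl", call))
    return out


def _sensitivity_block(truth, decision_sets, scen) -> dict:
    out = {}
    for name, dec in decision_sets.items():
        calls = [d.action for d in dec]
        cols = CLASS_ORDER if not scen.is_management else tuple(
            sorted(set(scen.action_set), key=lambda a: a.safety_rank))
        cm = confusion(truth, calls, col_labels=cols)
        block = {"confusion": cm.to_frame().to_dict(),
                 "confusion_row_normalized": cm.to_frame(normalized=True).to_dict()}
        if not scen.is_management:
            block["average_recall"] = average_recall(cm)
            block["accuracy"] = accuracy(cm)
            for c in CLASS_ORDER:
                k = int(cm.counts[c.index, c.index])
                n = int(cm.counts[c.index].sum())
                lo, hi = proportion_ci(k, n)
                block[f"sensitivity_{c.value}"] = {"value": k / n, "ci95": [lo, hi]}
        out[name] = block
    return out


def _management_block(truth, decision_sets) -> dict:
    """Excision-based TPR/FPR and malignant mismanagement rates per policy."""
    mal = np.array([t in MALIGNANT for t in truth])
    out = {}
    for name, dec in decision_sets.items():
        act = np.array([d.action for d in dec], dtype=object)
        excise = np.array([a is ManagementAction.EXCISE for a in act])
        dismissed_mal = np.array([a is ManagementAction.DISMISS for a in act]) & mal
        mel = np.array([t is DiagnosisLabel.MEL for t in truth])
        out[name] = {
            "tpr": float(excise[mal].mean()),
            "fpr": float(excise[~mal].mean()),
            "melanoma_tpr": float(excise[mel].mean()),
            "malignant_mismanaged": float(dismissed_mal.sum() / mal.sum()),
        }
    return out


def run_scenario(cfg: RunConfig) -> dict:
    """Run one clinical scenario end to end; returns (and optionally writes) a report."""
    scen = SCENARIOS[cfg.scenario]
    rewards = cfg.resolve_rewards()
    data_seed, train_seed, eval_seed, _ = _substream_seeds(cfg.seed)
    report: dict = {"scenario": cfg.scenario, **cfg.fingerprint()}
    tcfg = replace(cfg.train, seed=train_seed)

    if cfg.scenario == "patient_centered":
        cohort = sample_cohort(replace(cfg.cohort, seed=data_seed))
        records = cohort.all_records()
        truth = [r.true_label for r in records]
        thresholds = cfg.resolve_thresholds()
        log.info("patient scenario: %d patients, %d lesions",
                 cohort.n_patients, cohort.n_lesions)
        policy = train_q(cohort, rewards, TrainConfig.patient_defaults(
            seed=train_seed, max_steps=tcfg.max_steps, eval_period=tcfg.eval_period), scen)
        decision_sets = {
            "naive": run_policy_batch(records, scen, policy="naive"),
            "threshold": run_policy_batch(records, scen, thresholds=thresholds,
                                          policy="threshold"),
            "bayes": run_policy_batch(records, scen, rewards=rewards, policy="bayes"),
            "rl": rl_decisions(policy, cohort, scen),
        }
        report["patient_metrics"] = {
            name: {k: v for k, v in patient_metrics(cohort, dec).items()
                   if k != "excised_benign_per_patient"}
            for name, dec in decision_sets.items()}
        report["management"] = _management_block(truth, decision_sets)
        report["history"] = policy.history
        _write(cfg, report, decision_sets, records)
        return report

    gen = replace(cfg.generator, class_priors=_ISIC_PRIORS)
    rng = np.random.default_rng(data_seed)
    train_records = sample_states(gen, cfg.n_train, rng=rng, id_prefix="TRN")
    test_records = make_isic_fixture(cfg.generator, rng=rng)
    truth = [r.true_label for r in test_records]
    log.info("%s scenario: %d train, %d test lesions", cfg.scenario,
             len(train_records), len(test_records))

    policy = train_q(train_records, rewards, tcfg, scen)
    decision_sets = {"naive": run_policy_batch(test_records, scen, policy="naive"),
                     "bayes": run_policy_batch(test_records, scen, rewards=rewards,
                                               policy="bayes"),
                     "rl": rl_decisions(policy, test_records, scen)}
    if scen.is_management:
        thresholds = cfg.resolve_thresholds()
        decision_sets["threshold"] = run_policy_batch(
            test_records, scen, thresholds=thresholds, policy="threshold")

    report["policies"] = _sensitivity_block(truth, decision_sets, scen)
    if scen.is_management:
        report["management"] = _management_block(truth, decision_sets)
        p_mal = np.array([malignancy_probability(r.state.probabilities)
                          for r in test_records])
        mal = np.array([t in MALIGNANT for t in truth])
        roc = roc_and_operating_points(p_mal, mal, decision_sets, truth)
        report["roc"] = {
            "auc": roc["auc"],
            "operating_points": [{"policy": op.label, "fpr": op.fpr, "tpr": op.tpr}
                                 for op in roc["operating_points"]]}
    else:
        # prediction-uncertainty comparison: displayed SL probabilities vs
        # the RL policy's softmax(Q) predictive distributions
        if cfg.sl_temperature is not None:
            shown = make_isic_fixture(
                replace(cfg.generator, temperature=cfg.sl_temperature),
                rng=np.random.default_rng(data_seed + 1))
            P_sl = np.stack([r.state.probabilities for r in shown])
        else:
            P_sl = np.stack([r.state.probabilities for r in test_records])
        X, _ = state_matrix(test_records)
        P_rl = policy.predictive_distribution_batch(X)
        report["entropy"] = entropy_comparison(P_sl, P_rl, paired=True)
    report["history"] = policy.history
    _write(cfg, report, decision_sets, test_records)
    return report


def run_patient_cv(cfg: RunConfig, folds: int = 20) -> dict:
    """Patient-grouped cross-validation of the patient-centered RL model.

    Patients are partitioned into ``folds`` groups (no patient spans folds);
    each fold's lesions are decided by a policy trained on the remaining
    patients, and metrics are pooled over the union of held-out decisions.
    """
    scen = SCENARIOS["patient_centered"]
    rewards = cfg.resolve_rewards() if cfg.scenario == "patient_centered" \
        else default_reward_table("patient_centered")
    data_seed, train_seed, _, _ = _substream_seeds(cfg.seed)
    cohort = sample_cohort(replace(cfg.cohort, seed=data_seed))
    if folds > cohort.n_patients:
        raise ValueError(f"{folds} folds exceed {cohort.n_patients} patients")
    rng = np.random.default_rng(train_seed)
    order = rng.permutation(cohort.n_patients)
    assignment = np.empty(cohort.n_patients, dtype=int)
    for k, idx in enumerate(np.array_split(order, folds)):
        assignment[idx] = k

    pooled: list[PolicyDecision] = []
    fold_reports = []
    for k in range(folds):
        train_pat = tuple(p for i, p in enumerate(cohort.patients) if assignment[i] != k)
        test_pat = tuple(p for i, p in enumerate(cohort.patients) if assignment[i] == k)
        sub_train, sub_test = PatientCohort(train_pat), PatientCohort(test_pat)
        tcfg = TrainConfig.patient_defaults(seed=train_seed + k,
                                            max_steps=cfg.train.max_steps,
                                            eval_period=cfg.train.eval_period)
        policy = train_q(sub_train, rewards, tcfg, scen)
        dec = rl_decisions(policy, sub_test, scen)
        pooled.extend(dec)
        m = patient_metrics(sub_test, dec)
        fold_reports.append({"fold": k, "n_patients": sub_test.n_patients,
                             "melanoma_actions": m["melanoma_actions"]})
        log.info("fold %d/%d done (%d held-out patients)", k + 1, folds,
                 sub_test.n_patients)
    m = patient_metrics(cohort, pooled)
    m.pop("excised_benign_per_patient")
    return {**cfg.fingerprint(), "folds": folds, "fold_assignment_sizes":
            [int((assignment == k).sum()) for k in range(folds)],
            "pooled": m, "per_fold": fold_reports}


def _write(cfg: RunConfig, report: dict, decision_sets: dict,
           records: Sequence[LesionRecord]) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    frames = [decisions_to_frame(d) for d in decision_sets.values()]
    pd.concat(frames, ignore_index=True).to_csv(out / "decisions.csv", index=False)
    records_to_frame(list(records)).to_csv(out / "lesions.csv", index=False)
    log.info("wrote %s", out)
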