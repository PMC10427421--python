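"""Metrics and statistics: confusion matrices, entropy, ROC, paired tests.

Conventions used throughout:

* "average recall" (balanced accuracy) is the unweighted mean of per-class
  sensitivities over classes present in the truth — the headline accuracy
  measure for imbalanced lesion datasets; plain accuracy is reported separately.
* Entropy is Shannon entropy in bits, H(p) = -sum_i p_i log2 p_i with
  0 log 0 = 0, bounded by log2(7) ~ 2.807 for seven classes.
* The empirical ROC sweeps strict ">" cut-offs over the observed malignancy
  probabilities, so a pure malignancy-threshold policy's operating point lies
  exactly on the curve by construction.
* Proportion confidence intervals use the Wilson score method; paired
  proportions use McNemar with continuity correction (exact binomial when the
  discordant count is small).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core import (CLASS_ORDER, MALIGNANT, DiagnosisLabel, InvalidDistributionError,
                   ManagementAction, validate_distribution)
from .policies import PolicyDecision
from .records import PatientCohort

__all__ = ["ConfusionMatrix", "confusion", "class_sensitivity", "average_recall",
           "accuracy", "shannon_entropy", "entropy_comparison",
           "roc_curve_points", "OperatingPoint", "operating_point",
           "roc_and_operating_points", "auc", "proportion_ci",
           "paired_proportion_test", "patient_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts and row-normalized proportions; rows truth, columns calls."""

    col_labels: tuple
    counts: np.ndarray

    @property
    def row_labels(self) -> tuple:
        return CLASS_ORDER

    @property
    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / sums
        out[sums[:, 0] == 0] = np.nan
        return out

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.row_normalized if normalized else self.counts
        return pd.DataFrame(data, index=[r.value for r in CLASS_ORDER],
                            columns=[c.value for c in self.col_labels])


def confusion(truth: Sequence[DiagnosisLabel], called: Sequence,
              col_labels: tuple | None = None) -> ConfusionMatrix:
    """Tally (truth, call) pairs; calls may be diagnoses or management actions."""
    if len(truth) != len(called):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(called)} calls")
    if col_labels is None:
        if all(isinstance(c, DiagnosisLabel) for c in called):
            col_labels = CLASS_ORDER
        else:
            col_labels = tuple(sorted({c for c in called},
                                      key=lambda a: a.safety_rank))
    counts = np.zeros((len(CLASS_ORDER), len(col_labels)), dtype=int)
    col_idx = {c: j for j, c in enumerate(col_labels)}
    for t, c in zip(truth, called):
        counts[t.index, col_idx[c]] += 1
    return ConfusionMatrix(tuple(col_labels), counts)


def class_sensitivity(cm: ConfusionMatrix, c: DiagnosisLabel) -> float:
    """Row-normalized diagonal entry: the recall of class ``c``.

    For action-valued columns the "correct" column is the class's optimal
    management only when that column exists; diagnosis-valued columns use the
    matching diagnosis.
    """
    row = cm.counts[c.index]
    if row.sum() == 0:
        raise ValueError(f"no samples of class {c.value}")
    if c in cm.col_labels:
        return float(row[cm.col_labels.index(c)] / row.sum())
    raise ValueError(f"confusion matrix has no column for {c.value}")


def average_recall(cm: ConfusionMatrix) -> float:
    """Unweighted mean per-class recall over nonempty rows (balanced accuracy)."""
    vals = [class_sensitivity(cm, c) for c in CLASS_ORDER if cm.counts[c.index].sum() > 0]
    if not vals:
        raise ValueError("empty confusion matrix")
    return float(np.mean(vals))


def accuracy(cm: ConfusionMatrix) -> float:
    diag = sum(cm.counts[c.index, cm.col_labels.index(c)]
               for c in CLASS_ORDER if c in cm.col_labels)
    return float(diag / cm.counts.sum())


def shannon_entropy(p: np.ndarray) -> float | np.ndarray:
    """Shannon entropy in bits; accepts one distribution (any length) or a stack."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise InvalidDistributionError("probabilities must be nonnegative and sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.maximum(p, 1e-300)), 0.0)
    out = terms.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def entropy_comparison(pA: np.ndarray, pB: np.ndarray, paired: bool = True) -> dict:
    """Compare prediction uncertainty of two models over the same (or different) sets.

    Returns medians and quartiles of each model's entropies and, when paired, of
    the per-lesion deltas (B - A) together with a two-sided Wilcoxon
    signed-rank p-value (Mann-Whitney U when unpaired).
    """
    hA = np.atleast_1d(shannon_entropy(np.asarray(pA)))
    hB = np.atleast_1d(shannon_entropy(np.asarray(pB)))
    if len(hA) < 2 or len(hB) < 2:
        raise ValueError("need at least two distributions per group")
    out = {
        "median_A": float(np.median(hA)),
        "q25_A": float(np.percentile(hA, 25)), "q75_A": float(np.percentile(hA, 75)),
        "median_B": float(np.median(hB)),
        "q25_B": float(np.percentile(hB, 25)), "q75_B": float(np.percentile(hB, 75)),
        "paired": paired,
    }
    if paired:
        if len(hA) != len(hB):
            raise ValueError("paired comparison needs equal lengths")
        delta = hB - hA
        out.update({"median_delta": float(np.median(delta)),
                    "q25_delta": float(np.percentile(delta, 25)),
                    "q75_delta": float(np.percentile(delta, 75))})
        if np.allclose(delta, 0.0):
            out["p_value"] = 1.0
        else:
            out["p_value"] = float(stats.wilcoxon(hB, hA).pvalue)
    else:
        out["p_value"] = float(stats.mannwhitneyu(hB, hA, alternative="two-sided").pvalue)
    return out


@dataclass(frozen=True)
class OperatingPoint:
    fpr: float
    tpr: float
    label: str = ""


def roc_curve_points(p_mal: np.ndarray, truth_malignant: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC under the strict-">" excision rule.

    Cut-offs are the sorted unique observed scores plus sentinels; at cut-off t
    a lesion is "excised" iff its malignancy probability exceeds t.  Returns
    (fpr, tpr, cutoffs), fpr/tpr nonincreasing as the cut-off rises, with
    endpoints (1, 1) and (0, 0).
    """
    p_mal = np.asarray(p_mal, dtype=float)
    y = np.asarray(truth_malignant, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("truth must contain both malignant and benign lesions")
    cutoffs = np.concatenate([[-np.inf], np.unique(p_mal)])
    excised = p_mal[None, :] > cutoffs[:, None]
    tpr = excised[:, y].mean(axis=1)
    fpr = excised[:, ~y].mean(axis=1)
    return fpr, tpr, cutoffs


def auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(np.asarray(tpr)[order], np.asarray(fpr)[order]))


def operating_point(decisions: Sequence[PolicyDecision],
                    truth: Sequence[DiagnosisLabel], label: str = "") -> OperatingPoint:
    """(FPR, TPR) of a policy's excise decisions against the benign/malignant split."""
    if len(decisions) != len(truth):
        raise ValueError("decisions and truth lengths differ")
    exc = np.array([d.action is ManagementAction.EXCISE for d in decisions])
    mal = np.array([t in MALIGNANT for t in truth])
    return OperatingPoint(float(exc[~mal].mean()), float(exc[mal].mean()),
                          label or (decisions[0].policy_name if decisions else ""))


def roc_and_operating_points(p_mal, truth_malignant,
                             decision_sets: dict[str, Sequence[PolicyDecision]],
                             truth_labels: Sequence[DiagnosisLabel]) -> dict:
    fpr, tpr, cutoffs = roc_curve_points(p_mal, truth_malignant)
    points = [operating_point(d, truth_labels, name)
              for name, d in decision_sets.items()]
    return {"fpr": fpr, "tpr": tpr, "cutoffs": cutoffs,
            "auc": auc(fpr, tpr), "operating_points": points}


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def paired_proportion_test(b: int, c: int) -> tuple[float, float]:
    """McNemar test on the discordant-pair counts (b, c).

    Continuity-corrected chi-square for b + c >= 25; exact two-sided binomial
    otherwise.  Returns (statistic, p); the statistic is NaN for the exact form.
    """
    if b < 0 or c < 0 or b + c < 1:
        raise ValueError("need nonnegative discordant counts with b + c >= 1")
    if b + c < 25:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
        return float("nan"), min(p, 1.0)
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def patient_metrics(cohort: PatientCohort,
                    decisions: Sequence[PolicyDecision]) -> dict:
    """Patient-level management summary for the monitoring scenario.

    Reports per-patient excised-benign counts, how many patients lose more than
    three benign lesions, benign monitoring volume, and the action distribution
    over the cohort's melanomas.
    """
    by_id = {d.lesion_id: d for d in decisions}
    n_records = cohort.n_lesions
    if len(by_id) != len(decisions):
        raise ValueError("duplicate lesion ids in decisions")
    excised_benign_per_patient = {}
    monitored_benign = 0
    benign_total = 0
    mel_actions = {a: 0 for a in (ManagementAction.DISMISS, ManagementAction.MONITOR,
                                  ManagementAction.EXCISE)}
    action_totals: dict[ManagementAction, int] = {}
    for pid, lesions in cohort.patients:
        exc_benign = 0
        for rec in lesions:
            if rec.lesion_id not in by_id:
                raise ValueError(f"no decision for lesion {rec.lesion_id}")
            act = by_id[rec.lesion_id].action
            action_totals[act] = action_totals.get(act, 0) + 1
            benign = rec.true_label not in MALIGNANT
            if benign:
                benign_total += 1
                if act is ManagementAction.EXCISE:
                    exc_benign += 1
                elif act is ManagementAction.MONITOR:
                    monitored_benign += 1
            elif rec.true_label is DiagnosisLabel.MEL:
                mel_actions[act] = mel_actions.get(act, 0) + 1
        excised_benign_per_patient[pid] = exc_benign
    per_patient = np.array(list(excised_benign_per_patient.values()))
    return {
        "n_patients": cohort.n_patients,
        "n_lesions": n_records,
        "excised_benign_per_patient": excised_benign_per_patient,
        "total_excised_benign": int(per_patient.sum()),
        "patients_gt3_excised_benign": int((per_patient > 3).sum()),
        "monitored_benign": int(monitored_benign),
        "monitored_benign_fraction": float(monitored_benign / benign_total),
        "melanoma_actions": {a.value: int(k) for a, k in mel_actions.items()},
        "action_totals": {a.value: int(k) for a, k in action_totals.items()},
    }
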