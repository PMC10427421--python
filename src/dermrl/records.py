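"""In-memory containers for classifier outputs: lesions, states, patient cohorts.

A :class:`ClassifierState` is what a pretrained multiclass classifier emits for
one lesion — the 7-class probability vector, the pre-softmax logits and the
penultimate feature vector — and is the state the reinforcement-learning layer
operates on.  Datasets are round-tripped through tidy tables (one row per
lesion) so real classifier outputs can be supplied in the same schema as
simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CLASS_CODES, CLASS_ORDER, DiagnosisLabel, validate_distribution

__all__ = ["ClassifierState", "LesionRecord", "PatientCohort",
           "records_to_frame", "frame_to_records"]


@dataclass(frozen=True)
class ClassifierState:
    """One lesion's classifier output: probabilities, logits, features."""

    probabilities: np.ndarray  # (7,) on the simplex
    logits: np.ndarray         # (7,)
    features: np.ndarray       # (F,)

    def __post_init__(self):
        object.__setattr__(self, "probabilities",
                           validate_distribution(np.asarray(self.probabilities, float)))
        logits = np.asarray(self.logits, float)
        feats = np.asarray(self.features, float)
        if logits.shape != (len(CLASS_ORDER),):
            raise ValueError(f"logits must be a 7-vector, got {logits.shape}")
        if not (np.all(np.isfinite(logits)) and np.all(np.isfinite(feats))):
            raise ValueError("logits and features must be finite")
        object.__setattr__(self, "logits", logits)
        object.__setattr__(self, "features", feats)

    @property
    def feature_dim(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    true_label: DiagnosisLabel
    state: ClassifierState
    patient_id: str | None = None


@dataclass(frozen=True)
class PatientCohort:
    """Patients, each holding an ordered list of lesion records."""

    patients: tuple[tuple[str, tuple[LesionRecord, ...]], ...]

    def __post_init__(self):
        seen = set()
        for pid, lesions in self.patients:
            if not lesions:
                raise ValueError(f"patient {pid} has no lesions")
            for rec in lesions:
                if rec.lesion_id in seen:
                    raise ValueError(f"lesion {rec.lesion_id} assigned to more than one patient")
                seen.add(rec.lesion_id)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_lesions(self) -> int:
        return sum(len(l) for _, l in self.patients)

    def all_records(self) -> list[LesionRecord]:
        return [rec for _, lesions in self.patients for rec in lesions]

    def lesion_counts(self) -> np.ndarray:
        return np.array([len(l) for _, l in self.patients])


def records_to_frame(records: Sequence[LesionRecord]) -> pd.DataFrame:
    """Tidy table: ids, true label, p_*, logit_*, f_* columns."""
    if not records:
        raise ValueError("no records")
    fdim = records[0].state.feature_dim
    rows = []
    for r in records:
        if r.state.feature_dim != fdim:
            raise ValueError("inconsistent feature dimensions in dataset")
        row = {"lesion_id": r.lesion_id, "patient_id": r.patient_id or "",
               "true_label": r.true_label.value}
        row.update({f"p_{c}": v for c, v in zip(CLASS_CODES, r.state.probabilities)})
        row.update({f"logit_{c}": v for c, v in zip(CLASS_CODES, r.state.logits)})
        row.update({f"f_{j}": v for j, v in enumerate(r.state.features)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[LesionRecord]:
    p_cols = [f"p_{c}" for c in CLASS_CODES]
    l_cols = [f"logit_{c}" for c in CLASS_CODES]
    f_cols = sorted((c for c in df.columns if c.startswith("f_")),
                    key=lambda c: int(c.split("_", 1)[1]))
    out = []
    for _, row in df.iterrows():
        state = ClassifierState(row[p_cols].to_numpy(float),
                                row[l_cols].to_numpy(float),
                                row[f_cols].to_numpy(float))
        pid = str(row.get("patient_id", "")) or None
        if pid in ("nan", "None"):
            pid = None
        out.append(LesionRecord(str(row["lesion_id"]), DiagnosisLabel(row["true_label"]),
                                state, pid))
    return out
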