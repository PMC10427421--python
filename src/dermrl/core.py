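"""Domain vocabulary, reward tables, thresholds and scenario definitions.

The seven-class skin-lesion taxonomy (HAM10000 vocabulary) and the management
action space are fixed here, together with the file formats for expert-supplied
reward tables and probability thresholds.  Everything downstream (simulator,
Q-learning, policies, metrics) indexes vectors and matrices by the canonical
class order defined in :data:`CLASS_ORDER`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosisLabel",
    "ManagementAction",
    "RewardTable",
    "ThresholdSpec",
    "ScenarioSpec",
    "CLASS_ORDER",
    "MALIGNANT",
    "BENIGN",
    "SCENARIOS",
    "load_reward_table",
    "save_reward_table",
    "aggregate_reward_tables",
    "aggregate_thresholds",
    "optimal_management",
    "malignancy_probability",
    "validate_distribution",
]


class DiagnosisLabel(str, Enum):
    """Seven-class lesion taxonomy.

    MEL, BCC and AKIEC form the malignant-or-premalignant partition
    ("requires treatment"); BKL, NV, DF and VASC are benign.
    """

    MEL = "MEL"      # melanoma
    BCC = "BCC"      # basal cell carcinoma
    AKIEC = "AKIEC"  # actinic keratosis / intraepidermal carcinoma
    BKL = "BKL"      # benign keratinocytic lesion
    NV = "NV"        # melanocytic nevus
    DF = "DF"        # dermatofibroma
    VASC = "VASC"    # vascular lesion

    @property
    def index(self) -> int:
        return CLASS_ORDER.index(self)

    @property
    def is_malignant(self) -> bool:
        return self in MALIGNANT


class ManagementAction(str, Enum):
    """Management decisions, ordered by safety rank (cautious actions rank higher)."""

    DISMISS = "DISMISS"
    MONITOR = "MONITOR"
    TREAT_LOCALLY = "TREAT_LOCALLY"
    EXCISE = "EXCISE"

    @property
    def safety_rank(self) -> int:
        return _SAFETY_RANK[self]


CLASS_ORDER: tuple[DiagnosisLabel, ...] = (
    DiagnosisLabel.MEL,
    DiagnosisLabel.BCC,
    DiagnosisLabel.AKIEC,
    DiagnosisLabel.BKL,
    DiagnosisLabel.NV,
    DiagnosisLabel.DF,
    DiagnosisLabel.VASC,
)
CLASS_CODES: tuple[str, ...] = tuple(c.value for c in CLASS_ORDER)

MALIGNANT: frozenset[DiagnosisLabel] = frozenset(
    {DiagnosisLabel.MEL, DiagnosisLabel.BCC, DiagnosisLabel.AKIEC}
)
BENIGN: frozenset[DiagnosisLabel] = frozenset(CLASS_ORDER) - MALIGNANT

_SAFETY_RANK = {
    ManagementAction.DISMISS: 0,
    ManagementAction.MONITOR: 1,
    ManagementAction.TREAT_LOCALLY: 2,
    ManagementAction.EXCISE: 3,
}


class RewardTableError(ValueError):
    """Malformed or mismatched reward-table input."""


class InvalidDistributionError(ValueError):
    """Probability vector off the simplex."""


def _canon_label(code: str):
    code = code.strip().upper()
    if code in DiagnosisLabel.__members__:
        return DiagnosisLabel[code]
    if code in ManagementAction.__members__:
        return ManagementAction[code]
    raise RewardTableError(f"unknown label {code!r}; expected one of "
                           f"{CLASS_CODES + tuple(a.value for a in ManagementAction)}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A clinical decision scenario: its action set and optimal-management map."""

    name: str
    action_set: tuple
    optimal_action_map: Mapping[DiagnosisLabel, ManagementAction] | None

    @property
    def is_management(self) -> bool:
        return self.optimal_action_map is not None

    def action_index(self, action) -> int:
        return self.action_set.index(action)


def _management_map(actions: set[ManagementAction]) -> dict:
    m = {}
    for d in CLASS_ORDER:
        if d in (DiagnosisLabel.MEL, DiagnosisLabel.BCC):
            m[d] = ManagementAction.EXCISE
        elif d is DiagnosisLabel.AKIEC:
            # local therapy where the scenario offers it, otherwise excise:
            # AKIEC counts with the malignant class in the binary scenario
            m[d] = (ManagementAction.TREAT_LOCALLY
                    if ManagementAction.TREAT_LOCALLY in actions
                    else ManagementAction.EXCISE)
        else:
            m[d] = ManagementAction.DISMISS
    return m


SCENARIOS: dict[str, ScenarioSpec] = {
    "diagnosisRL": ScenarioSpec("diagnosisRL", CLASS_ORDER, None),
    "binary": ScenarioSpec(
        "binary",
        (ManagementAction.DISMISS, ManagementAction.EXCISE),
        _management_map({ManagementAction.DISMISS, ManagementAction.EXCISE}),
    ),
    "multiclass_therapy": ScenarioSpec(
        "multiclass_therapy",
        (ManagementAction.DISMISS, ManagementAction.TREAT_LOCALLY, ManagementAction.EXCISE),
        _management_map({ManagementAction.DISMISS, ManagementAction.TREAT_LOCALLY,
                         ManagementAction.EXCISE}),
    ),
    "patient_centered": ScenarioSpec(
        "patient_centered",
        (ManagementAction.DISMISS, ManagementAction.MONITOR, ManagementAction.EXCISE),
        _management_map({ManagementAction.DISMISS, ManagementAction.MONITOR,
                         ManagementAction.EXCISE}),
    ),
}


@dataclass(frozen=True)
class RewardTable:
    """Reward/penalty matrix indexed by (true diagnosis, predicted diagnosis or action).

    Rows always follow :data:`CLASS_ORDER`; columns follow the canonical order of
    whichever label set they carry (diagnoses, or a scenario's action set).
    Penalties are asymmetric by design — missing a melanoma is costlier than
    excising a nevus — so no symmetry is assumed or enforced.
    """

    col_labels: tuple
    values: np.ndarray  # shape (7, n_cols), float
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(CLASS_ORDER), len(self.col_labels)):
            raise RewardTableError(
                f"shape {v.shape} does not match 7x{len(self.col_labels)} labels")
        if not np.all(np.isfinite(v)):
            raise RewardTableError("reward table contains non-finite entries")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def row_labels(self) -> tuple:
        return CLASS_ORDER

    def reward(self, truth: DiagnosisLabel, col) -> float:
        return float(self.values[truth.index, self.col_labels.index(col)])

    def matches_scenario(self, scenario: ScenarioSpec) -> bool:
        return set(self.col_labels) == set(scenario.action_set)

    def reordered_for(self, scenario: ScenarioSpec) -> "RewardTable":
        """Columns permuted into the scenario's action order."""
        if not self.matches_scenario(scenario):
            raise RewardTableError(
                f"column set {sorted(c.value for c in self.col_labels)} does not match "
                f"scenario {scenario.name!r} actions "
                f"{sorted(a.value for a in scenario.action_set)}")
        perm = [self.col_labels.index(a) for a in scenario.action_set]
        return RewardTable(scenario.action_set, self.values[:, perm], self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=[r.value for r in CLASS_ORDER],
                            columns=[c.value for c in self.col_labels])


def _canonical_col_order(cols: Sequence) -> tuple:
    if all(isinstance(c, DiagnosisLabel) for c in cols):
        return tuple(sorted(cols, key=lambda c: c.index))
    if all(isinstance(c, ManagementAction) for c in cols):
        return tuple(sorted(cols, key=lambda c: c.safety_rank))
    raise RewardTableError("columns mix diagnoses and management actions")


def load_reward_table(source: str | Path, expected_columns: Iterable | None = None,
                      provenance: str | None = None) -> RewardTable:
    """Read a reward table from CSV (header = columns, first field = row label) or JSON.

    JSON form: ``{"columns": [...], "rows": {"MEL": [...], ...}, "provenance": "..."}``.
    Raises :class:`RewardTableError` on unknown labels, missing rows, non-numeric
    cells, or a column set that does not match ``expected_columns``.
    """
    source = Path(source)
    if source.suffix.lower() == ".json":
        obj = json.loads(source.read_text())
        cols = [_canon_label(c) for c in obj["columns"]]
        rows = {_canon_label(r): v for r, v in obj["rows"].items()}
        prov = obj.get("provenance", source.name)
    else:
        try:
            df = pd.read_csv(source, index_col=0)
        except Exception as exc:  # noqa: BLE001 - wrap any parse failure
            raise RewardTableError(f"cannot parse {source}: {exc}") from exc
        cols = [_canon_label(c) for c in df.columns]
        rows = {_canon_label(r): df.loc[r].tolist() for r in df.index}
        prov = source.name
    missing = [d.value for d in CLASS_ORDER if d not in rows]
    if missing:
        raise RewardTableError(f"missing ground-truth rows: {missing}")
    extra = [r for r in rows if not isinstance(r, DiagnosisLabel)]
    if extra:
        raise RewardTableError(f"row labels must be diagnoses, got {extra}")
    col_order = _canonical_col_order(cols)
    perm = [cols.index(c) for c in col_order]
    try:
        mat = np.array([[float(rows[d][j]) for j in perm] for d in CLASS_ORDER])
    except (TypeError, ValueError) as exc:
        raise RewardTableError(f"non-numeric cell in {source}: {exc}") from exc
    table = RewardTable(col_order, mat, provenance if provenance is not None else prov)
    if expected_columns is not None:
        expected = {_canon_label(c) if isinstance(c, str) else c for c in expected_columns}
        if set(col_order) != expected:
            raise RewardTableError(
                f"scenario mismatch: table columns {[c.value for c in col_order]} "
                f"!= expected {sorted(c.value for c in expected)}")
    return table


def save_reward_table(table: RewardTable, dest: str | Path) -> None:
    dest = Path(dest)
    if dest.suffix.lower() == ".json":
        obj = {
            "columns": [c.value for c in table.col_labels],
            "rows": {d.value: table.values[i].tolist() for i, d in enumerate(CLASS_ORDER)},
            "provenance": table.provenance,
        }
        dest.write_text(json.dumps(obj, indent=1))
    else:
        table.to_frame().to_csv(dest)


@dataclass(frozen=True)
class ThresholdSpec:
    """Probability cut-offs driving the threshold-hierarchy policy.

    All thresholds live in [0, 1] and are compared strictly (">", the decision
    escalates only when a probability *exceeds* its cut-off).  ``monitor`` is the
    patient-scenario malignancy cut-off below the excision rules; lesions above it
    are monitored rather than dismissed.
    """

    melanoma_excise: float | None = None
    malignancy_excise: float | None = None
    bcc_excise: float | None = None
    akiec_local: float | None = None
    monitor: float | None = None
    fallback_action: ManagementAction = ManagementAction.DISMISS

    _FIELDS = ("melanoma_excise", "malignancy_excise", "bcc_excise", "akiec_local", "monitor")

    def __post_init__(self):
        for name in self._FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold {name}={v} outside [0, 1]")
        if (self.monitor is not None and self.malignancy_excise is not None
                and self.monitor > self.malignancy_excise):
            raise ValueError("monitor threshold must not exceed the malignancy excision threshold")

    @classmethod
    def from_json(cls, source: str | Path) -> "ThresholdSpec":
        obj = json.loads(Path(source).read_text())
        fallback = obj.pop("fallback_action", "DISMISS")
        obj.pop("provenance", None)
        return cls(fallback_action=ManagementAction[fallback], **obj)

    def to_json(self, dest: str | Path, provenance: str = "") -> None:
        obj = {k: getattr(self, k) for k in self._FIELDS if getattr(self, k) is not None}
        obj["fallback_action"] = self.fallback_action.value
        if provenance:
            obj["provenance"] = provenance
        Path(dest).write_text(json.dumps(obj, indent=1))


def _agg(stack: np.ndarray, method: str) -> np.ndarray:
    if method == "median":
        return np.median(stack, axis=0)
    if method == "minimum":
        return np.min(stack, axis=0)
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_reward_tables(tables: Sequence[RewardTable], method: str = "median") -> RewardTable:
    """Cell-wise median (or minimum) of several experts' reward tables.

    The median of an even count is the midpoint of the two central values.
    """
    if not tables:
        raise ValueError("need at least one reward table")
    cols = tables[0].col_labels
    if any(t.col_labels != cols for t in tables):
        raise RewardTableError("cannot aggregate tables with differing column labels")
    stack = np.stack([t.values for t in tables])
    prov = f"{method} of {len(tables)} tables"
    return RewardTable(cols, _agg(stack, method), prov)


def aggregate_thresholds(specs: Sequence[ThresholdSpec], method: str = "median") -> ThresholdSpec:
    """Field-wise median (or minimum) across experts' threshold specs.

    A field must be defined by all experts or by none.
    """
    if not specs:
        raise ValueError("need at least one threshold spec")
    out = {}
    for name in ThresholdSpec._FIELDS:
        vals = [getattr(s, name) for s in specs]
        defined = [v for v in vals if v is not None]
        if defined and len(defined) != len(vals):
            raise ValueError(f"threshold field {name!r} defined for only some experts")
        if defined:
            out[name] = float(_agg(np.asarray(defined, dtype=float), method))
    return ThresholdSpec(fallback_action=specs[0].fallback_action, **out)


def optimal_management(d: DiagnosisLabel, scenario: ScenarioSpec) -> ManagementAction:
    """Optimal action for a ground-truth diagnosis under a management scenario.

    Melanoma and BCC call for excision; AKIEC for local therapy where the
    scenario offers it (excision otherwise); every benign diagnosis is dismissed.
    """
    if not scenario.is_management:
        raise ValueError(f"scenario {scenario.name!r} has no management mapping")
    return scenario.optimal_action_map[d]


def validate_distribution(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != len(CLASS_ORDER):
        raise InvalidDistributionError(f"expected 7 probabilities, got shape {p.shape}")
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=-1) - 1.0) > atol):
        raise InvalidDistributionError("probabilities must be nonnegative and sum to 1")
    return p


def malignancy_probability(p: np.ndarray) -> float | np.ndarray:
    """Overall malignancy probability: p[MEL] + p[BCC] + p[AKIEC].

    Accepts a single 7-vector or an (n, 7) array.
    """
    p = validate_distribution(p)
    idx = [d.index for d in (DiagnosisLabel.MEL, DiagnosisLabel.BCC, DiagnosisLabel.AKIEC)]
    out = p[..., idx].sum(axis=-1)
    return float(out) if out.ndim == 0 else out
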