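"""Synthetic classifier-output generator with analytically known posteriors.

Emulates the outputs of a pretrained seven-class lesion classifier without any
images: features for a lesion of class ``d`` are drawn from an isotropic
Gaussian ``N(mu_d, I)`` whose means sit ``class_separation`` apart on orthogonal
axes, and the logits are the *exact* log-posterior of that generative model.
With ``temperature=1`` and no label noise the emitted probabilities are
therefore perfectly calibrated, which makes the Bayes-optimal action for any
reward table computable in closed form — the oracle the Q-learning tests are
checked against.  Two distortion knobs break calibration on purpose:

``temperature``
    probabilities = softmax(logits / T).  T < 1 sharpens them, mimicking the
    overconfidence typical of deep classifiers; T > 1 flattens them.
``label_noise``
    probability of replacing a record's ground-truth label by a uniformly
    random other class, leaving the state untouched.

``confusion_pairs`` pulls selected class means toward each other; the default
elevates melanoma–nevus overlap, the clinically dominant confusion.  Cohort
generation reproduces a sequential-monitoring dataset: 524 patients, 7,375
lesions of which 55 are early melanomas, 6–51 lesions per patient (median 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import CLASS_ORDER, DiagnosisLabel
from .records import ClassifierState, LesionRecord, PatientCohort

__all__ = ["GeneratorConfig", "CohortConfig", "class_means", "sample_states",
           "posterior_logits", "make_isic_fixture", "sample_cohort",
           "ISIC_TEST_COUNTS", "MONITORING_COMPOSITION"]

# Per-class test-set composition of the external validation set (n = 1,511).
ISIC_TEST_COUNTS: dict[DiagnosisLabel, int] = {
    DiagnosisLabel.MEL: 171,
    DiagnosisLabel.BCC: 93,
    DiagnosisLabel.AKIEC: 43,
    DiagnosisLabel.BKL: 217,
    DiagnosisLabel.NV: 908,
    DiagnosisLabel.DF: 44,
    DiagnosisLabel.VASC: 35,
}

# Monitoring cohort composition: 55 early melanomas and 7,320 benign lesions
# (7,213 nevi, 53 keratinocytic + 3 unclassified benign lesions folded into BKL,
# 31 dermatofibromas, 20 vascular) from 524 patients.
MONITORING_COMPOSITION: dict[DiagnosisLabel, int] = {
    DiagnosisLabel.MEL: 55,
    DiagnosisLabel.NV: 7213,
    DiagnosisLabel.BKL: 56,
    DiagnosisLabel.DF: 31,
    DiagnosisLabel.VASC: 20,
}


@dataclass(frozen=True)
class GeneratorConfig:
    class_priors: tuple = tuple([1.0 / 7] * 7)
    feature_dim: int = 16
    class_separation: float = 2.7
    confusion_pairs: tuple = ((DiagnosisLabel.MEL, DiagnosisLabel.NV, 0.40),)
    temperature: float = 1.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        pr = np.asarray(self.class_priors, dtype=float)
        if pr.shape != (7,) or np.any(pr < 0) or abs(pr.sum() - 1.0) > 1e-9:
            raise ValueError("class_priors must be a 7-vector on the simplex")
        object.__setattr__(self, "class_priors", tuple(pr))
        if self.feature_dim < 7:
            raise ValueError("feature_dim must be >= 7 so class means can be orthogonal")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for a, b, ov in self.confusion_pairs:
            if not (0.0 <= ov <= 1.0):
                raise ValueError(f"overlap factor {ov} outside [0, 1]")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError("label_noise must be a probability")


def class_means(config: GeneratorConfig) -> np.ndarray:
    """(7, F) matrix of class-conditional feature means.

    Class ``d`` starts at ``class_separation`` along axis ``d``; each confusion
    pair then pulls both means toward their midpoint by half the overlap factor
    (overlap 1 makes them coincide).
    """
    mu = np.zeros((7, config.feature_dim))
    for i in range(7):
        mu[i, i] = config.class_separation
    base = mu.copy()
    for a, b, ov in config.confusion_pairs:
        i, j = a.index, b.index
        mid = 0.5 * (base[i] + base[j])
        mu[i] = base[i] + ov * (mid - base[i])
        mu[j] = base[j] + ov * (mid - base[j])
    return mu


def posterior_logits(features: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Exact log-posterior (up to an additive constant per row) of the generative model."""
    mu = class_means(config)
    pr = np.asarray(config.class_priors)
    # floor zero priors so logits stay finite; the class still gets ~0 posterior
    log_prior = np.log(np.maximum(pr, 1e-12))
    # N(mu_d, I): log p(x|d) = -||x - mu_d||^2 / 2 + const
    return log_prior + features @ mu.T - 0.5 * np.sum(mu**2, axis=1)


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _build_records(labels: np.ndarray, config: GeneratorConfig,
                   rng: np.random.Generator, id_prefix: str,
                   patient_ids: Sequence[str] | None = None) -> list[LesionRecord]:
    n = len(labels)
    mu = class_means(config)
    feats = mu[labels] + rng.standard_normal((n, config.feature_dim))
    logits = posterior_logits(feats, config)
    logits = logits - logits.mean(axis=1, keepdims=True)  # fix the additive gauge
    probs = _softmax(logits / config.temperature)
    if config.label_noise > 0:
        flip = rng.random(n) < config.label_noise
        shift = rng.integers(1, 7, size=n)
        labels = labels.copy()
        labels[flip] = (labels[flip] + shift[flip]) % 7
    out = []
    for k in range(n):
        state = ClassifierState(probs[k], logits[k], feats[k])
        pid = patient_ids[k] if patient_ids is not None else None
        out.append(LesionRecord(f"{id_prefix}{k:06d}", CLASS_ORDER[labels[k]], state, pid))
    return out


def sample_states(config: GeneratorConfig, n: int,
                  rng: np.random.Generator | None = None,
                  id_prefix: str = "L") -> list[LesionRecord]:
    """Draw ``n`` lesion records: label ~ priors, features ~ N(mu_label, I)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = rng.choice(7, size=n, p=np.asarray(config.class_priors))
    return _build_records(labels, config, rng, id_prefix)


def make_isic_fixture(config: GeneratorConfig | None = None,
                      rng: np.random.Generator | None = None) -> list[LesionRecord]:
    """Test set with the external validation composition (1,511 lesions).

    Class priors in the posterior are set to the composition proportions so the
    emitted probabilities stay calibrated for this label mix.
    """
    config = config or GeneratorConfig()
    counts = np.array([ISIC_TEST_COUNTS[d] for d in CLASS_ORDER])
    priors = counts / counts.sum()
    config = replace(config, class_priors=tuple(priors))
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = np.repeat(np.arange(7), counts)
    rng.shuffle(labels)
    return _build_records(labels, config, rng, "ISIC")


@dataclass(frozen=True)
class CohortConfig:
    """Patient-cohort generator settings for the monitoring scenario."""

    n_patients: int = 524
    composition: str = "exact_paper"           # or "stochastic"
    class_counts: Mapping[DiagnosisLabel, int] = field(
        default_factory=lambda: dict(MONITORING_COMPOSITION))
    melanoma_rate: float = 55 / 7375           # stochastic mode only
    lesions_per_patient_mean: float = 14.1     # stochastic mode only
    lesion_range: tuple[int, int] = (6, 51)
    # truncated NB(size, mean) on [6, 51] has median 12 and mean ~14.1 here,
    # matching the cohort's printed per-patient profile before exact adjustment
    nb_size: float = 2.0                       # negative-binomial dispersion
    nb_mean: float = 11.0                      # pre-truncation mean (exact mode)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0


def _truncated_nb_counts(n: int, mean: float, size: float,
                         lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Per-patient lesion counts from a negative binomial truncated to [lo, hi]."""
    p = size / (size + mean)
    support = np.arange(lo, hi + 1)
    pmf = stats.nbinom.pmf(support, size, p)
    pmf = pmf / pmf.sum()
    return rng.choice(support, size=n, p=pmf)


def _adjust_to_total(counts: np.ndarray, total: int, lo: int, hi: int,
                     rng: np.random.Generator) -> np.ndarray:
    counts = counts.copy()
    diff = total - counts.sum()
    guard = 0
    while diff != 0:
        step = 1 if diff > 0 else -1
        room = np.flatnonzero((counts < hi) if step > 0 else (counts > lo))
        if room.size == 0:
            raise ValueError("composition infeasible for the per-patient count range")
        take = rng.choice(room, size=min(abs(diff), room.size), replace=False)
        counts[take] += step
        diff = total - counts.sum()
        guard += 1
        if guard > 10_000:
            raise RuntimeError("count adjustment failed to converge")
    return counts


def sample_cohort(cc: CohortConfig | None = None) -> PatientCohort:
    """Generate a monitoring cohort of patients with grouped lesion records.

    ``exact_paper`` composition reproduces the printed cohort exactly: 524
    patients, 7,375 lesions, 55 melanomas, per-patient counts in [6, 51] drawn
    from a truncated negative binomial (median approximately 12) and then
    adjusted to hit the exact total.  ``stochastic`` mode draws composition and
    counts from the configured rates instead.
    """
    cc = cc or CohortConfig()
    rng = np.random.default_rng(cc.seed)
    lo, hi = cc.lesion_range
    if cc.composition == "exact_paper":
        label_multiset = np.concatenate([
            np.full(k, d.index) for d, k in cc.class_counts.items()])
        total = label_multiset.size
        if not (lo * cc.n_patients <= total <= hi * cc.n_patients):
            raise ValueError(
                f"{total} lesions cannot be split over {cc.n_patients} patients "
                f"with {lo}..{hi} lesions each")
        counts = _truncated_nb_counts(cc.n_patients, cc.nb_mean, cc.nb_size, lo, hi, rng)
        counts = _adjust_to_total(counts, total, lo, hi, rng)
        labels = label_multiset.copy()
        rng.shuffle(labels)
    elif cc.composition == "stochastic":
        counts = _truncated_nb_counts(cc.n_patients, cc.lesions_per_patient_mean,
                                      cc.nb_size, lo, hi, rng)
        total = int(counts.sum())
        benign = {d: k for d, k in cc.class_counts.items() if d is not DiagnosisLabel.MEL}
        bsum = sum(benign.values())
        p = np.zeros(7)
        p[DiagnosisLabel.MEL.index] = cc.melanoma_rate
        for d, k in benign.items():
            p[d.index] = (1.0 - cc.melanoma_rate) * k / bsum
        labels = rng.choice(7, size=total, p=p)
    else:
        raise ValueError(f"unknown composition mode {cc.composition!r}")

    # calibrate the posterior to the cohort's empirical label mix
    priors = np.bincount(labels, minlength=7) / labels.size
    gen = replace(cc.generator, class_priors=tuple(priors))
    patient_ids = np.repeat([f"P{i:04d}" for i in range(cc.n_patients)], counts)
    records = _build_records(labels, gen, rng, "MON", patient_ids=list(patient_ids))

    patients, start = [], 0
    for i, c in enumerate(counts):
        patients.append((f"P{i:04d}", tuple(records[start:start + int(c)])))
        start += int(c)
    return PatientCohort(tuple(patients))
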