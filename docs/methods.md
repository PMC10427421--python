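# Methods

## Decision model

Diagnostic management is modeled as a Markov decision process over classifier
states. A state is the concatenation `[features ‖ logits ‖ probabilities]` of a
pretrained classifier's outputs for one lesion; actions are either the seven
diagnoses or a scenario's management set (binary: dismiss/excise; multiclass
therapy: dismiss/treat locally/excise; patient-centered:
dismiss/monitor/excise); the reward for action `a` on a lesion with ground
truth `d` is the expert table entry `R[d, a]`. Actions do not influence which
lesion is seen next, so rewards are immediate and the default discount is
γ = 0; the trainer nevertheless implements the general discounted target
`r + γ·max_a Q_target(s', a)` for experimentation with γ > 0, where the
next-state convention is the next lesion drawn in the episode with a terminal
flag at episode end (inert at γ = 0).

Under calibrated probabilities the optimal policy has the closed form
`argmax_a Σ_d p(d|s) R[d, a]`. This Bayes rule is implemented independently of
the learner (`policies.bayes_policy`) and serves as the oracle in tests: a
converged Q-policy on calibrated synthetic data must agree with it on ≥95% of
held-out states. For the binary scenario the Bayes rule reduces to a single
cut-off on malignancy probability,
`p* = (R[ben,DIS] − R[ben,EXC]) / (R[mal,EXC] − R[mal,DIS] + R[ben,DIS] − R[ben,EXC])`,
giving a second, fully closed-form oracle.

## Q-network and training

The Q-function is a small multilayer perceptron: a 256-unit fully connected
ReLU layer processes the feature vector; its output is concatenated with the
logits *and the probabilities* and fed to a linear head with one unit per
action. Design note: the head sees the probabilities because the expected
reward of an action is linear in the predictive distribution, so the exact
Q-function is representable by the head alone and the hidden branch only
models residual structure. With the probabilities omitted the network must
reconstruct a softmax from noisy 0/1-style reward samples; in controlled
regression diagnostics that variant plateaued around 92–94% agreement with the
Bayes rule — an approximation limit, not a training-length issue — while the
adopted wiring reaches 98–100%.

Training follows the standard deep Q-learning recipe: ε-greedy behavior
(constant ε = 0.2), a FIFO replay buffer of 10,000 transitions, one
minibatch (32) Huber-loss TD update every 4 environment steps (35 in the
patient scenario), a target network copied every 8,000 steps (5,800 patient),
Adam at learning rate 0.025, dropout 0.05 on the hidden layer during training.
Episode construction: lesion-level episodes are fixed-length (default 50,
valid range 12–250 — length has little effect) random draws from the training
pool; patient-level episodes are all lesions of one patient, normalized
position-wise by the patient's mean state vector (positions with
mean magnitude < 1e-8 are left raw) and ordered by descending malignancy
probability, descending so the high-stakes lesions anchor the episode. An
80/20 split (by patient in patient mode) provides a validation stream; mean
greedy reward on it is logged every `eval_period` steps and can drive optional
early stopping.

Two numerical choices matter for convergence:

* **Reward normalization.** Tables are scaled to `max |R| = 1` during training
  and Q-values rescaled on readout. The Huber transition width is δ = 1; with
  unscaled rewards spanning ±8 most TD residuals sit in the linear zone, where
  the Huber minimizer is a biased M-estimate between mean and median of the
  sampled rewards, and greedy argmaxes drift from the expected-reward rule
  (~6 points of Bayes agreement in our measurements). Scaling rewards into the
  unit quadratic zone is argmax-invariant and restores the mean as the
  minimizer.
* **Polyak (tail) averaging.** Because reward samples stay noisy forever,
  Adam's weights wander in a steady-state noise ball around the optimum. The
  deployed policy uses an exponential moving average of the weights
  (decay 0.999) accumulated over the gradient updates; the training dynamics
  (behavior policy, target network) use the raw weights throughout.

Determinism: one `numpy` generator seeded from `TrainConfig.seed` drives
initialization, episode draws, ε-exploration, replay sampling and dropout, so
identical data + config + seed reproduce bit-identical parameters. Pipeline
runs fan a single global seed into named substreams (data, training,
evaluation) via `SeedSequence`, and every artifact embeds the config hash,
seed and class-order fingerprint. Policy archives record the class order and
refuse to load under a different one.

## Baseline policies

* **Naive:** top-1 predicted class, mapped to its optimal management
  (MEL/BCC → excise; AKIEC → local therapy where offered, else excise; benign
  → dismiss). Ties in the argmax resolve to the lower canonical class index.
* **Threshold hierarchy:** ordered strict-`>` cut-offs — melanoma
  probability, overall malignancy probability (p(MEL)+p(BCC)+p(AKIEC)), BCC
  probability, AKIEC probability (local therapy where available), then in the
  patient scenario a monitoring cut-off on malignancy probability; fallback is
  dismissal, since the hierarchy enumerates only escalation conditions.
  Strict exceedance is deliberate and documented because boundary cases
  differ between ">" and "≥".
* **Bayes:** expected-reward argmax as above; exact ties resolve toward the
  more cautious action (higher safety rank: excise > treat locally > monitor >
  dismiss), or the lower canonical index for diagnosis actions.

Expert inputs aggregate cell-wise (tables) or field-wise (thresholds) by
median — midpoint rule for even counts — or by minimum for the deliberately
aggressive low-threshold variant.

## Synthetic classifier outputs

The simulator emulates the *outputs* of a supervised lesion classifier, not
skin images. Features for class `d` are `N(μ_d, I)` in 16 dimensions (any
dimension ≥ 7 works) with `μ_d` at distance `class_separation` along
orthogonal axes; confusion pairs pull selected means toward their shared
midpoint by an overlap factor. Logits are the exact log-posterior of this
generative model, so temperature-1 probabilities are perfectly calibrated —
the property all oracle equivalences rest on. Distortion knobs: temperature
(sharpen/flatten, emulating the overconfidence of deep classifiers) and label
noise (mislabeled ground truth).

Default conditions: `class_separation = 2.7` with MEL–NV overlap 0.40. These
were fixed so the naive policy on the 1,511-lesion test composition matches
the working profile of a strong published seven-class dermatoscopy classifier
— melanoma sensitivity ≈ 61% (driven by melanomas called nevi) and average
recall ≈ 78% — and were not adjusted afterwards. Under these conditions the
calibrated probabilities have a median Shannon entropy of ≈ 0.30 bits
(IQR ≈ 0.09–0.82), so no temperature distortion is applied in the entropy
comparisons; the Q-policy's softmax predictive distributions (normalized
exponential of the Q-vector in original reward units — one of several
reasonable conventions, adopted and flagged as such) have median entropy
≈ 1.8 bits under the asymmetric table.

Fixture generators reproduce printed compositions exactly: the test set
(MEL 171, BCC 93, AKIEC 43, BKL 217, NV 908, DF 44, VASC 35; total 1,511) and
the monitoring cohort (524 patients; 7,375 lesions; 55 early melanomas; 7,213
nevi; 53 + 3 unclassified benign lesions folded into BKL, the closest benign
keratinocytic class; 31 dermatofibromas; 20 vascular lesions). Per-patient
lesion counts come from a negative binomial (size 2.0, mean 11) truncated to
[6, 51] — median 12, truncated mean ≈ 14.1 — then adjusted by random ±1 steps
within bounds to hit the exact 7,375 total.

What the simulator does **not** model: image content, feature correlations of
real CNN embeddings, miscalibration structure beyond a global temperature,
label noise correlated with difficulty, and site or scanner effects. Passing
oracle-equivalence tests therefore shows the learner recovers the optimal
decision rule *when the classifier is calibrated and its features are
informative*; it does not certify performance on any real dermatoscopy
dataset.

## Reward and threshold defaults

The bundled tables (`src/dermrl/data/*_synthetic.*`) are authored defaults
labelled synthetic: diagnosis rewards give +4 for a correct melanoma and −8
for a melanoma called benign, graded smaller penalties for the other
malignancies, and mild penalties for benign-to-malignant confusion; the
patient table penalizes dismissing a melanoma (−8) far more than monitoring
one (−2); the thresholds place melanoma excision at 0.2, overall malignancy at
0.5, BCC at 0.4, AKIEC local therapy at 0.4 and monitoring at 0.1. They are
configuration, not elicited data; swap in your own experts' files and combine
them with `aggregate_reward_tables` / `aggregate_thresholds` (median or
minimum).

## Evaluation conventions

"Average recall" is the unweighted mean per-class sensitivity (balanced
accuracy) over classes present in the truth — the right headline number for a
dataset that is 60% nevi — with plain accuracy reported separately. Entropy is
Shannon entropy in bits with 0·log 0 ≡ 0. The empirical ROC sweeps strict-`>`
cut-offs over observed malignancy probabilities, which makes a pure
malignancy-threshold policy's operating point lie on the curve *exactly*, a
property tested to machine precision. Proportion CIs use the Wilson score
interval (the CI method for the reference sensitivities is not documented, so
digit-level CI agreement is not claimed). Paired proportions use McNemar with
continuity correction, falling back to the exact binomial when discordant
pairs number fewer than 25; paired continuous comparisons use the Wilcoxon
signed-rank test.

## Problem sizes and known limitations

End-to-end checks train on 10,000 simulated lesions for 120,000 environment
steps (≈ 30,000 gradient updates, under a minute per policy on one CPU) and
evaluate on 2,000 held-out states or the 1,511-lesion fixture; these sizes
were chosen as the point where agreement with the analytic oracle saturates.
The patient-centered learner is exercised mechanically (episode construction,
normalization, grouped 20-fold cross-validation, lesion-count conservation)
but is not claimed to reach its oracle: with 55 melanomas among 7,375
normalized states the reward signal is extremely sparse, and its validation
reward remains visibly noisy at these training lengths. Hyperparameters
mirror the reference recipe rather than a fresh search; γ > 0 paths are
implemented but only lightly exercised.
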