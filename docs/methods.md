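# Methods

`conformxplain` studies a question that arises whenever deep models are used
to classify conformational states from molecular-dynamics (MD) data: when
the class distribution is heavily skewed and the model is explained post
hoc, which parts of the analysis can be trusted? The package implements the
full analysis loop — trajectory featurization, marker-distance labeling,
class-imbalance mitigation, a 1D-CNN classifier with tree baselines,
residue-level attribution, and an assessment layer for explanation
robustness, stability, and cross-method consensus — on synthetic receptor
trajectories with *planted* ground truth, so the whole chain can be scored
on whether it recovers what was put in.

## The synthetic generator

The generator emulates the statistical structure of β2AR-like receptor MD
data without any physics:

* **Geometry.** Each of `n_residues` (default 282) residues is a single 3D
  point — the analog of a residue center of mass — drawn once per ensemble
  from an isotropic Gaussian cloud (σ = 10 Å), then perturbed per frame by
  isotropic noise (`noise_sd`, default 0.3 Å). Frames are i.i.d.
  classification samples, not an autocorrelated time series; the analysis
  treats frames as independent samples, so temporal correlation is
  deliberately not modeled.
* **States.** A single marker-residue pair (defaults to the midpoints of
  helices H3 and H6, the analog of the R131–L272 Cα distance) defines the
  conformational state: distance ≥ 14 Å ⇒ active, ≤ 8.5 Å ⇒ inactive,
  strictly between ⇒ intermediate. Per-state marker distances are sampled
  from truncated normals — active N(15.5, 0.5) on [14, ∞), inactive
  N(7.5, 0.5) on (0, 8.5], intermediate N(11.0, 1.5) on (8.5, 14) — a broad
  intermediate band between two sharp extremes. The second marker residue
  is then *placed geometrically* on a fixed line through the first at the
  sampled distance, so distance-based relabeling reproduces the generating
  labels with 100% agreement by construction.
* **Imbalance.** Class proportions default to (0.10, 0.80, 0.10) for
  (active, intermediate, inactive), apportioned by largest remainder: the
  intermediate state heavily predominates, as it does in real receptor
  ensembles that linger in transitional conformations.
* **Planted signal.** Eight residues inside the H1 segment receive
  state-specific displacements of magnitude 2.0 Å (random direction per
  state, zero for the intermediate state). These are the ground truth that
  attribution methods are scored against. With 2.0 Å shifts against 0.3 Å
  noise each planted residue is individually informative — the recovery
  test asks whether the *pipeline* surfaces them, not whether the signal is
  detectable at all.
* **Scale.** The default ensemble has 600 frames. This is the desk-scale
  study condition used throughout the tests and the worked examples; all
  sizes are configurable.

What the generator does **not** reproduce: force-field physics, membrane
context, autocorrelated dynamics, atom-level structure (residues are
points; the atom-level center-of-mass path exists for real data), or the
residue-residue covariance of a folded chain. A passing recovery test
therefore shows the analysis machinery is sound, not that it would resolve
arbitrarily subtle signals in real MD data.

## Featurization and labeling

Each frame becomes one vector of length 3R (846 for 282 residues),
residue-major then (x, y, z). Centers of mass accept optional atomic
masses; without them the geometric center is used (which of the two the
original receptor analyses used is typically unstated; the choice is
exposed). Labeling thresholds are inclusive toward the extreme states
(≥ 14 active, ≤ 8.5 inactive). Features are left raw by default — no
z-scoring is applied in featurization; the CNN standardizes internally (see
below), and any user-level scaling should be fit on the training split
only.

## Imbalance mitigation

Six strategies, implemented from first principles with Euclidean k-NN on
the raw features:

* **SMOTE** (k = 5): minority classes are filled to the majority count with
  points x + λ(x′ − x), λ ~ U[0,1], x′ one of x's k nearest same-class
  neighbors.
* **ADASYN**: per-sample quotas proportional to the fraction of other-class
  points among each sample's k nearest neighbors over the whole dataset, so
  synthesis concentrates near class boundaries; interpolation as SMOTE. If
  a minority class's neighborhood is pure (all ratios zero — common when
  classes are well separated in high dimension), quotas fall back to
  uniform with a warning.
* **SMOTEENN**: SMOTE, then edited-nearest-neighbors cleaning that removes
  majority-class samples contradicted by ≥ 2 of their 3 nearest neighbors.
  ENN edits only the pre-oversampling majority class by default
  (configurable), reading ENN as a cleaner of majority overlap.
* **NearMiss** (versions 1–3): distance-ranked undersampling of majority
  classes to the minority count; ties broken by lowest index via stable
  sorts.
* **Random over/undersampling**: duplication and uniform deletion.
* **Weighted loss**: no resampling; class weights w_c = 1 − n_c/N,
  renormalized to mean 1, multiply each sample's cross-entropy term. The
  formula is the inverse-frequency reading of the weighting scheme
  ("the class's share of the imbalance"), which makes rarer classes
  strictly heavier.

Multi-class handling: oversamplers treat each non-majority class against
the rest, with neighbor search for interpolation restricted to the class's
own members. Resampling is applied to the training split only; the
experiment driver enforces this by splitting before resampling.

## The classifier

`Conv1DClassifier` is a scikit-learn-style estimator around a numpy
network: the 3R feature vector is treated as a length-3R, single-channel
sequence passed through convolution blocks (filters, kernel, max-pool),
dense layers with ReLU and dropout, and a softmax head. Design choices
that matter:

* **Internal standardization.** The first layer is a fixed per-feature
  affine map (x − μ)/σ fitted on the training data. Keeping it inside the
  network means gradients and relevance propagate through it exactly;
  relevance passes through unchanged because a per-feature monotone
  rescaling does not move contribution between features.
* **Bias-free conv/dense layers** (default). With ReLU activations and no
  biases the epsilon-rule LRP pass conserves the target logit almost
  exactly (observed gaps ~1e-5 relative); the standardization layer
  supplies the centering that biases would otherwise provide. Biases can
  be enabled per estimator.
* **Architecture default**: two conv blocks (24 then 48 filters, kernel 7,
  max-pool 3), one dense layer of 64, dropout 0.2. Chosen as the smallest
  stack that cleanly separates the synthetic states and keeps full sweeps
  cheap on one CPU; all layer sizes are configuration, not assumptions.
* **Optimization**: Adam at 1e-3, batch 64, up to 25 epochs, early stopping
  (patience 5) on an internal 10% stratified holdout carved from the
  training data — never on the external validation split, which is reserved
  for metrics and explanations. All randomness flows from one integer seed;
  training is bit-reproducible for a fixed seed since the stack is pure
  numpy.
* **Class order** is fixed as (active, intermediate, inactive) everywhere.

Decision-tree and random-forest baselines are scikit-learn estimators
(CART/Gini; bagged trees) exposed through `train_tree` / `train_forest`
with Gini importances for the global-explanation comparison.

## Attribution

All methods reduce to one signed value per residue.

* **LRP** (epsilon rule): relevance starts at the target-class logit
  (softmax excluded) and is redistributed backward; each layer's stabilizer
  is ε = 1e-6 × mean|pre-activation|. Max-pooling routes relevance
  winner-take-all; ReLU and dropout pass through. Conservation
  |ΣR − logit| stays within 5% of the logit (and is near-exact for the
  default bias-free network).
* **Saliency**: |∂ logit / ∂ input|, summed over each residue's three
  coordinates; non-negative by construction.
* **LIME-style surrogate**: residues (not coordinates) are the
  interpretable units; 2000 random on/off masks replace toggled-off
  residues with training-mean coordinates, samples are weighted by
  exp(−d²/kw²) on the Euclidean distance (kw defaults to the median
  perturbation distance), and a ridge regression of the target-class
  probability on the mask yields the coefficients.
* **Kernel-SHAP-style sampling**: residues are the players; absent residues
  take the mean background coordinates (20 training samples). Coalitions
  are sampled from the Shapley-kernel size distribution (budget
  2M + 512 by default) and solved by constrained weighted least squares;
  when the full coalition space fits the budget the enumeration is
  exhaustive and the attributions are exact Shapley values. Local accuracy
  (Σφ + base = model output) holds to 1e-2 under enumeration.
* **Permutation importance**: per-class accuracy drop from shuffling each
  residue's columns; negative values are reported as-is.

Explanations are computed on validation samples only and directed at each
sample's *true* class (the alternative — the predicted class — differs only
on misclassified samples; the true-class convention keeps the per-state
maps interpretable as "what characterizes this state").

Grouping coordinates by residue for the surrogate methods is both what
makes 282-player Shapley sampling tractable and what matches residue-level
contribution maps; coordinate-level values from LRP/saliency are summed per
residue for the same reason.

## Assessment

* **Metrics**: confusion matrix, one-vs-rest precision/recall/F1 with
  support-weighted averages, accuracy, multiclass MCC (the R_K statistic;
  degenerate denominators yield 0 with a warning), and one-vs-all ROC AUC
  by trapezoidal integration.
* **Robustness**: cosine similarity between explanations of x and
  x + N(0, 0.5²), per sample, averaged over a seeded validation subset.
* **Stability**: mean pairwise cosine similarity among 2–5 repetitions of
  the same explanation; repetitions re-draw only the explainer's internal
  randomness, so any deterministic explainer (LRP, saliency, or a
  fixed-seed surrogate) scores exactly 1. Scores are compared per sample
  and then averaged — averaging maps first could mask anticorrelated
  per-sample instability.
* **IQR relevance**: per state, residues whose mean contribution falls
  outside the Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR (multiplier
  configurable); both signs are kept.
* **Consensus**: full Venn decomposition of 2–4 named relevant-residue
  sets, along both axes (across explainers for a fixed mitigation, and
  across mitigations for a fixed explainer).
* **Recovery**: precision/recall of the union of per-state relevant
  residues against the planted informative set. The marker residues are
  genuinely state-defining but are not counted as planted, which caps
  precision by design; recall is the primary recovery number.

## Numerical and degenerate-input conventions

k-NN ties are broken by lowest index (stable sorts throughout). Quartiles
use linear interpolation. Zero explanation vectors are skipped (with a
count) in robustness scoring and are an error in cosine similarity. A
contribution-map row for a state with no samples is NaN with a warning and
yields an empty relevant set. Training aborts with diagnostics on
non-finite loss.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the default study conditions:
600-frame, 282-residue ensembles; recovery is averaged over 5 generator
seeds for each of {none, SMOTEENN, ADASYN, weighted loss}; SHAP stability
uses 3 repetitions on 50 validation samples with a 600-coalition budget;
the chance-AUC check uses 10,000 label-independent score triples.

## Known limitations

* Synthetic frames are i.i.d.; no Markov-state or kinetic structure.
* The CNN is a compact numpy implementation — adequate and exactly
  reproducible at these scales, but not a GPU training stack.
* LIME/SHAP surrogate quality depends on the mask distribution and
  background choice; the defaults are documented above rather than tuned
  per dataset.
* Exact reproduction of metrics reported for the real receptor dataset is
  out of scope: those numbers depend on external MD data; the package's
  claims are the property-level ones its tests compute.
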