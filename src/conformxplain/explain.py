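"""Residue-level attribution of classifier decisions.

Five routes to "which residues drove this prediction":

* LRP — epsilon-rule layer-wise relevance propagation through the CNN,
  signed, approximately conserving the target logit;
* saliency — absolute gradient of the target logit w.r.t. the input,
  non-negative by construction;
* LIME-style local surrogate — proximity-weighted ridge regression of the
  class probability on random residue on/off masks;
* Kernel-SHAP-style sampling — Shapley-kernel-weighted regression over
  residue coalitions, with the exact enumeration used when feasible;
* permutation importance — per-class accuracy drop from shuffling features.

For the surrogate methods the interpretable units are residues, not
coordinates: the three coordinates of a residue toggle together, making
coalition sampling over 282 players tractable and matching residue-level
contribution maps. Coordinate-level values from LRP/saliency are summed per
residue.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .synthdata import STATES


@dataclass
class ExplanationVector:
    """Per-residue signed contributions of one sample toward one class."""

    values: np.ndarray
    target_class: str
    method: str
    sample_id: int | None = None

    def validate(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("explanation contains non-finite values")


@dataclass
class ContributionMap:
    """states x residues mean contributions for one method/setting."""

    values: np.ndarray
    states: tuple
    method: str
    imbalance_method: str | None = None
    n_samples_per_state: dict | None = None


def _per_residue(values_per_feature: np.ndarray) -> np.ndarray:
    """Sum feature-level values over each residue's three coordinates."""
    v = np.asarray(values_per_feature, dtype=float)
    if v.shape[-1] % 3:
        raise ValueError("feature length is not a multiple of 3")
    return v.reshape(*v.shape[:-1], -1, 3).sum(axis=-1)


def _rng_for(random_state):
    """Fresh seeded generator for an int seed; shared stream for a
    Generator (so repeated calls re-draw reproducibly)."""
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


class LRPExplainer:
    """Epsilon-rule LRP on a :class:`~conformxplain.classifier.Conv1DClassifier`."""

    method = "lrp"

    def __init__(self, model, eps_scale=1e-6):
        self.model = model
        self.eps_scale = eps_scale

    def explain(self, x, target, sample_id=None) -> ExplanationVector:
        x = np.atleast_2d(np.asarray(x, dtype=np.float32))
        R, _ = self.model.relevance(x, target, eps_scale=self.eps_scale)
        return ExplanationVector(_per_residue(R[0]), target, self.method,
                                 sample_id)

    def conservation_gap(self, x, target):
        """(|sum R - logit|, |logit|) for the conservation check."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float32))
        R, logit = self.model.relevance(x, target,
                                        eps_scale=self.eps_scale)
        return float(abs(R[0].sum() - logit[0])), float(abs(logit[0]))


class SaliencyExplainer:
    """Absolute input gradient of the target logit, summed per residue."""

    method = "saliency"

    def __init__(self, model):
        self.model = model

    def explain(self, x, target, sample_id=None) -> ExplanationVector:
        x = np.atleast_2d(np.asarray(x, dtype=np.float32))
        g = self.model.input_gradient(x, target)
        return ExplanationVector(_per_residue(np.abs(g[0])), target,
                                 self.method, sample_id)


class LimeExplainer:
    """Local linear surrogate over residue on/off masks.

    Perturbed samples replace toggled-off residues with training-mean
    coordinates; samples are weighted by exp(-d^2 / kernel_width^2) on the
    Euclidean distance to the original point, and a ridge regression of the
    target-class probability on the binary mask yields one signed
    coefficient per residue. ``kernel_width=None`` uses the median
    perturbation distance.
    """

    method = "lime"

    def __init__(self, model, X_train, n_perturb=2000, kernel_width=None,
                 alpha=1.0, random_state=None):
        self.model = model
        self.mean_coords = np.asarray(X_train, dtype=float).mean(axis=0)
        self.n_perturb = n_perturb
        self.kernel_width = kernel_width
        self.alpha = alpha
        self.random_state = random_state

    def explain(self, x, target, sample_id=None) -> ExplanationVector:
        x = np.asarray(x, dtype=float).ravel()
        n_residues = len(x) // 3
        if self.n_perturb < n_residues + 2:
            raise ValueError(
                f"n_perturb={self.n_perturb} too small; need at least "
                f"n_residues + 2 = {n_residues + 2}")
        rng = _rng_for(self.random_state)
        masks = rng.integers(0, 2, size=(self.n_perturb, n_residues))
        masks[0] = 1                       # include the original point
        off = np.repeat(masks == 0, 3, axis=1)
        Xp = np.where(off, self.mean_coords, x)
        d = np.linalg.norm(Xp - x, axis=1)
        kw = self.kernel_width
        if kw is None:
            kw = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
        weights = np.exp(-(d ** 2) / (kw ** 2))
        probs = self.model.predict_proba(Xp)
        t_idx = self.model.class_index(target)
        surrogate = Ridge(alpha=self.alpha)
        surrogate.fit(masks, probs[:, t_idx], sample_weight=weights)
        return ExplanationVector(surrogate.coef_.copy(), target,
                                 self.method, sample_id)


def _shapley_kernel_weights(M, sizes):
    w = (M - 1) / (sizes * (M - sizes))
    from scipy.special import comb
    return w / comb(M, sizes)


class KernelShapExplainer:
    """Shapley-value attribution by kernel-weighted coalition regression.

    Players are residues; an "absent" residue takes the mean background
    coordinates. When the full coalition space (2^M - 2) fits within
    ``n_coalitions`` the enumeration is exhaustive and the result is exact;
    otherwise coalitions are sampled with probability proportional to the
    Shapley kernel over sizes. The sum of attributions plus the base value
    reproduces the model output at x (local accuracy; exact under
    enumeration, approximate under sampling).
    """

    method = "shap"

    def __init__(self, model, background, n_coalitions=None,
                 random_state=None):
        self.model = model
        self.background = np.atleast_2d(np.asarray(background, dtype=float))
        if self.background.shape[0] == 0:
            raise ValueError("background must be non-empty")
        self.n_coalitions = n_coalitions
        self.random_state = random_state

    def _masks(self, M, rng):
        budget = self.n_coalitions
        if budget is None:
            budget = 2 * M + 512
        if budget < M + 2:
            raise ValueError(
                f"n_coalitions={budget} too small; need at least "
                f"M + 2 = {M + 2}")
        total = 2 ** M - 2 if M < 32 else np.inf
        if total <= budget:
            masks = np.zeros((int(total), M), dtype=float)
            for row, subset in enumerate(
                    itertools.chain.from_iterable(
                        itertools.combinations(range(M), s)
                        for s in range(1, M))):
                masks[row, list(subset)] = 1.0
            sizes = masks.sum(axis=1)
            weights = _shapley_kernel_weights(M, sizes)
            return masks, weights
        sizes_all = np.arange(1, M)
        p = (M - 1) / (sizes_all * (M - sizes_all))
        p = p / p.sum()
        sizes = rng.choice(sizes_all, size=budget, p=p)
        masks = np.zeros((budget, M), dtype=float)
        for i, s in enumerate(sizes):
            masks[i, rng.choice(M, size=s, replace=False)] = 1.0
        return masks, np.ones(budget)

    def explain(self, x, target, sample_id=None) -> ExplanationVector:
        x = np.asarray(x, dtype=float).ravel()
        M = len(x) // 3
        rng = _rng_for(self.random_state)
        base = self.background.mean(axis=0)
        t_idx = self.model.class_index(target)
        f0 = float(self.model.predict_proba(base[None, :])[0, t_idx])
        fx = float(self.model.predict_proba(x[None, :])[0, t_idx])
        masks, weights = self._masks(M, rng)
        on = np.repeat(masks == 1, 3, axis=1)
        Xm = np.where(on, x, base)
        v = self.model.predict_proba(Xm)[:, t_idx] - f0

        # Weighted least squares with the constraint sum(phi) = fx - f0,
        # eliminated by substituting the last player.
        total = fx - f0
        Z = masks[:, :-1] - masks[:, -1:]
        target_v = v - masks[:, -1] * total
        sw = np.sqrt(weights)
        A = Z * sw[:, None]
        b = target_v * sw
        phi_part, *_ = np.linalg.lstsq(A, b, rcond=None)
        phi = np.empty(M)
        phi[:-1] = phi_part
        phi[-1] = total - phi_part.sum()
        self.base_value_ = f0
        self.model_output_ = fx
        return ExplanationVector(phi, target, self.method, sample_id)


def permutation_importance(model, X, y, seed=0, n_repeats=2,
                           group_by_residue=True):
    """Per-class accuracy drop after shuffling each feature (group).

    importance[class, group] = accuracy on that class's samples before
    shuffling minus after, averaged over ``n_repeats``; negative values
    (noise) are reported as-is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = [c for c in STATES if c in set(y)] or sorted(set(y))
    base_pred = np.asarray(model.predict(X))
    base_acc = {c: (base_pred[y == c] == c).mean() for c in classes}
    if group_by_residue:
        groups = [list(range(3 * r, 3 * r + 3))
                  for r in range(X.shape[1] // 3)]
    else:
        groups = [[j] for j in range(X.shape[1])]
    out = np.zeros((len(classes), len(groups)))
    for gi, cols in enumerate(groups):
        drops = np.zeros(len(classes))
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(len(X))
            Xp[:, cols] = X[perm][:, cols]
            pred = np.asarray(model.predict(Xp))
            for ci, c in enumerate(classes):
                drops[ci] += base_acc[c] - (pred[y == c] == c).mean()
        out[:, gi] = drops / n_repeats
    return classes, out


def aggregate_class_map(explanations, labels, method=None,
                        imbalance_method=None) -> ContributionMap:
    """Average per-sample explanations into a states x residues map.

    Each state's row is the mean over the samples whose (true) label is
    that state, each explained toward its own class.
    """
    explanations = list(explanations)
    labels = np.asarray(labels)
    if not explanations:
        raise ValueError("no explanations to aggregate")
    lengths = {len(e.values) for e in explanations}
    methods = {e.method for e in explanations}
    if len(lengths) != 1 or len(methods) != 1:
        raise ValueError("explanations must share one method and length")
    n_residues = lengths.pop()
    values = np.full((len(STATES), n_residues), np.nan)
    n_per_state = {}
    vec = np.stack([e.values for e in explanations])
    for si, state in enumerate(STATES):
        mask = labels == state
        n_per_state[state] = int(mask.sum())
        if mask.any():
            values[si] = vec[mask].mean(axis=0)
        else:
            warnings.warn(f"no samples with label {state!r}; map row is NaN",
                          stacklevel=2)
    return ContributionMap(values=values, states=STATES,
                           method=method or methods.pop(),
                           imbalance_method=imbalance_method,
                           n_samples_per_state=n_per_state)


def explain_validation_set(explainer, X, y, sample_ids=None):
    """Explain every sample toward its own (true) class."""
    X = np.asarray(X)
    y = np.asarray(y)
    ids = sample_ids if sample_ids is not None else range(len(y))
    return [explainer.explain(X[i], y[i], sample_id=sid)
            for i, sid in zip(range(len(y)), ids)]


EXPLAINER_NAMES = ("lrp", "saliency", "lime", "shap", "perm")


def make_explainer(name, model, X_train, seed=0, **kwargs):
    """Factory for the named attribution method."""
    if name == "lrp":
        return LRPExplainer(model, **kwargs)
    if name == "saliency":
        return SaliencyExplainer(model)
    if name == "lime":
        return LimeExplainer(model, X_train, random_state=seed, **kwargs)
    if name == "shap":
        rng = np.random.default_rng(seed)
        bg_size = min(20, len(X_train))
        bg = np.asarray(X_train)[rng.choice(len(X_train), size=bg_size,
                                            replace=False)]
        return KernelShapExplainer(model, bg, random_state=seed, **kwargs)
    raise ValueError(f"unknown explainer {name!r}; "
                     f"expected one of {EXPLAINER_NAMES}")
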