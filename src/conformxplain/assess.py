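"""Evaluation layer: classification metrics, explanation robustness and
stability, IQR relevance filtering, consensus intersections, and recovery
against planted ground truth.

Rates come from the confusion matrix (scikit-learn under the hood); the
multiclass MCC is the R_K statistic. Robustness perturbs inputs with
Gaussian noise and compares explanations by cosine similarity; stability
repeats explanations on identical inputs, re-drawing only the explainer's
internal randomness.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .explain import ContributionMap
from .synthdata import STATES, GroundTruth


@dataclass
class MetricsTable:
    """Per-class and weighted classification rates plus MCC and AUC."""

    confusion: np.ndarray
    labels: tuple
    precision: dict
    recall: dict
    f1: dict
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float
    mcc: float | None = None
    auc: dict | None = None

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }


@dataclass
class RobustnessConfig:
    """Settings for the robustness/stability assessment."""

    noise_sd: float = 0.5
    stability_repeats: int = 3
    subset_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 2 <= self.stability_repeats <= 5:
            raise ValueError("stability_repeats must lie in [2, 5]")


@dataclass
class RelevantSet:
    """Per-state residues whose mean contribution lies outside the Tukey
    fences Q1 - m*IQR / Q3 + m*IQR of that state's distribution."""

    by_state: dict
    iqr_multiplier: float = 1.5

    def union(self) -> set:
        out = set()
        for members in self.by_state.values():
            out |= {residue for residue, _, _ in members}
        return out


def _ordered_labels(y_true, y_pred):
    present = set(np.asarray(y_true)) | set(np.asarray(y_pred))
    ordered = [c for c in STATES if c in present]
    ordered += sorted(present - set(STATES))
    return ordered


def confusion_and_rates(y_true, y_pred, labels=None) -> MetricsTable:
    """Confusion matrix with one-vs-rest precision/recall/F1 per class,
    support-weighted averages, and accuracy."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    labels = list(labels) if labels is not None else _ordered_labels(
        y_true, y_pred)
    cm = skm.confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    wp, wr, wf, _ = skm.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0)
    return MetricsTable(
        confusion=cm, labels=tuple(labels),
        precision={c: float(p) for c, p in zip(labels, prec)},
        recall={c: float(r) for c, r in zip(labels, rec)},
        f1={c: float(v) for c, v in zip(labels, f1)},
        weighted_precision=float(wp), weighted_recall=float(wr),
        weighted_f1=float(wf),
        accuracy=float(skm.accuracy_score(y_true, y_pred)))


def mcc(y_true, y_pred) -> float:
    """Multiclass Matthews correlation (the R_K statistic), in [-1, 1].

    Degenerate denominators (e.g. a single predicted class) yield 0 with a
    warning, matching the convention for an uninformative prediction.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("mcc requires at least two classes in y_true")
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        value = skm.matthews_corrcoef(y_true, np.asarray(y_pred))
    return float(value)


def roc_auc_ova(y_true, scores, labels=None) -> dict:
    """One-vs-all AUC per class by trapezoidal integration (tied scores
    averaged). Classes absent from y_true get NaN."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != len(y_true):
        raise ValueError("scores must be n_samples x n_classes")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    labels = list(labels) if labels is not None else _ordered_labels(
        y_true, y_true)
    if scores.shape[1] != len(labels):
        raise ValueError(
            f"scores have {scores.shape[1]} columns for {len(labels)} "
            "classes")
    out = {}
    for j, c in enumerate(labels):
        pos = y_true == c
        if pos.all() or not pos.any():
            out[c] = float("nan")
            continue
        out[c] = float(skm.roc_auc_score(pos.astype(int), scores[:, j]))
    return out


def cosine_similarity(a, b) -> float:
    """cos(angle) between two non-zero vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def robustness_score(explainer, X_subset, targets,
                     cfg: RobustnessConfig) -> float:
    """Mean cosine similarity between explanations of clean and
    Gaussian-perturbed inputs (x vs x + N(0, noise_sd^2)), same class.

    Samples whose explanation is a zero vector are skipped; the skip count
    is recorded on ``robustness_score.last_skipped``.
    """
    cfg.validate()
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=float))
    rng = np.random.default_rng(cfg.seed)
    sims, skipped = [], 0
    for x, target in zip(X_subset, targets):
        noisy = x + rng.normal(0.0, cfg.noise_sd, size=x.shape)
        e_clean = explainer.explain(x, target).values
        e_noisy = explainer.explain(noisy, target).values
        try:
            sims.append(cosine_similarity(e_clean, e_noisy))
        except ValueError:
            skipped += 1
    robustness_score.last_skipped = skipped
    if not sims:
        raise ValueError("all explanations were zero vectors")
    return float(np.mean(sims))


def stability_score(explainer, X_subset, targets,
                    cfg: RobustnessConfig) -> float:
    """Mean pairwise cosine similarity among repeated explanations of
    identical inputs.

    Each repetition re-draws only the explainer's internal randomness: a
    deterministic explainer (or one with a fixed integer seed) therefore
    scores exactly 1.0.
    """
    cfg.validate()
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=float))
    sims = []
    for x, target in zip(X_subset, targets):
        reps = [explainer.explain(x, target).values
                for _ in range(cfg.stability_repeats)]
        for a, b in itertools.combinations(reps, 2):
            sims.append(cosine_similarity(a, b))
    return float(np.mean(sims))


def iqr_relevant(cmap: ContributionMap, multiplier=1.5) -> RelevantSet:
    """Residues whose mean contribution lies outside the Tukey fences.

    Per state: members below Q1 - m*IQR or above Q3 + m*IQR of that
    state's contribution distribution, with the contribution and its sign.
    """
    by_state = {}
    for si, state in enumerate(cmap.states):
        row = np.asarray(cmap.values[si], dtype=float)
        if not np.isfinite(row).all():
            by_state[state] = []
            continue
        q1, q3 = np.percentile(row, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        members = [(int(r), float(row[r]), int(np.sign(row[r])))
                   for r in np.where((row < lo) | (row > hi))[0]]
        by_state[state] = members
    return RelevantSet(by_state=by_state, iqr_multiplier=multiplier)


def consensus(named_sets: dict) -> dict:
    """Venn decomposition of 2-4 named residue sets.

    Returns every non-empty combination of names mapped to its exclusive
    region (members in exactly those sets), with counts, plus the full
    intersection.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("consensus expects between 2 and 4 named sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names
                                         if c not in combo))
            members = sorted(inside - outside)
            regions["&".join(combo)] = {
                "members": members, "count": len(members)}
    full = sorted(set.intersection(*sets.values()))
    return {"regions": regions,
            "intersection": {"members": full, "count": len(full)}}


def recovery_score(relevant: RelevantSet, truth: GroundTruth) -> dict:
    """Precision/recall of the union of relevant residues against the
    planted informative residues."""
    predicted = relevant.union()
    planted = set(truth.informative_residues)
    tp = len(predicted & planted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(planted) if planted else 0.0
    return {"precision": precision, "recall": recall,
            "n_predicted": len(predicted), "n_planted": len(planted)}
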