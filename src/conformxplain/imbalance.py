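"""Class-imbalance mitigation: SMOTE, ADASYN, SMOTEENN, NearMiss, random
over/undersampling, and inverse-frequency class weights.

All resamplers are implemented from first principles (Euclidean k-NN on the
raw feature space) and follow the imblearn-style estimator convention: set
parameters in ``__init__``, call ``fit_resample(X, y)``. Originals keep
their labels; synthetic rows are flagged in the returned provenance array.
Resampling is meant for the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

ORIGINAL, SYNTHETIC = "original", "synthetic"


@dataclass
class ResamplerConfig:
    """Declarative choice of mitigation method and its hyperparameters."""

    method: str = "none"
    k_neighbors: int = 5
    enn_neighbors: int = 3
    nearmiss_version: int = 1
    seed: int = 0

    _METHODS = ("smote", "adasyn", "smoteenn", "nearmiss", "random_over",
                "random_under", "weighted_loss", "none")

    def validate(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"expected one of {self._METHODS}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.nearmiss_version not in (1, 2, 3):
            raise ValueError("nearmiss_version must be 1, 2 or 3")


@dataclass
class ResampledDataset:
    """Post-mitigation features/labels, provenance flags, optional weights."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray
    class_weights: dict | None = None


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2D with one label per row")
    return X, y


def _class_counts(y):
    classes, counts = np.unique(y, return_counts=True)
    return dict(zip(classes.tolist(), counts.tolist()))


def _knn_within(Xc, k):
    """Indices of each row's k nearest same-set neighbors (self excluded).

    Ties are broken by lowest index (stable sort on distances).
    """
    d = cdist(Xc, Xc)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


class SMOTE:
    """Synthetic minority oversampling by convex interpolation.

    Each class below the target count is filled with points x + lam *
    (x_nn - x), lam ~ U[0, 1], where x is a class member and x_nn one of
    its ``k_neighbors`` nearest same-class neighbors.
    """

    def __init__(self, k_neighbors=5, target_counts=None, random_state=None):
        self.k_neighbors = k_neighbors
        self.target_counts = target_counts
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"k_neighbors": self.k_neighbors,
                "target_counts": self.target_counts,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.random_state)
        counts = _class_counts(y)
        targets = self.target_counts or {
            c: max(counts.values()) for c in counts}
        new_X, new_y = [X], [y]
        prov = [np.full(len(y), ORIGINAL, dtype=object)]
        for c in sorted(counts):
            need = targets.get(c, counts[c]) - counts[c]
            if need <= 0:
                continue
            if counts[c] <= self.k_neighbors:
                raise ValueError(
                    f"class {c!r} has {counts[c]} samples, not enough for "
                    f"k_neighbors={self.k_neighbors}; use a smaller k")
            Xc = X[y == c]
            nn = _knn_within(Xc, self.k_neighbors)
            base = rng.integers(0, len(Xc), size=need)
            pick = rng.integers(0, self.k_neighbors, size=need)
            lam = rng.random(need)
            neigh = Xc[nn[base, pick]]
            synth = Xc[base] + lam[:, None] * (neigh - Xc[base])
            new_X.append(synth)
            new_y.append(np.full(need, c, dtype=y.dtype))
            prov.append(np.full(need, SYNTHETIC, dtype=object))
        return ResampledDataset(np.vstack(new_X), np.concatenate(new_y),
                                np.concatenate(prov).astype(str))


class ADASYN:
    """Adaptive synthetic oversampling.

    Per-sample generation quotas are proportional to the fraction of
    other-class points among each minority sample's ``k_neighbors`` nearest
    neighbors (searched over the whole dataset), so synthesis concentrates
    near class boundaries. Interpolation itself follows SMOTE within the
    sample's own class.
    """

    def __init__(self, k_neighbors=5, random_state=None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"k_neighbors": self.k_neighbors,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def generation_ratios(self, X, y, cls):
        """Normalized boundary ratios r_i for members of class ``cls``."""
        X, y = _check_Xy(X, y)
        idx = np.where(y == cls)[0]
        d = cdist(X[idx], X)
        d[np.arange(len(idx)), idx] = np.inf
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k_neighbors]
        r = (y[order] != cls).mean(axis=1)
        return r

    def fit_resample(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.random_state)
        counts = _class_counts(y)
        majority = max(counts.values())
        new_X, new_y = [X], [y]
        prov = [np.full(len(y), ORIGINAL, dtype=object)]
        for c in sorted(counts):
            need = majority - counts[c]
            if need <= 0:
                continue
            if counts[c] <= self.k_neighbors:
                raise ValueError(
                    f"class {c!r} has {counts[c]} samples, not enough for "
                    f"k_neighbors={self.k_neighbors}; use a smaller k")
            r = self.generation_ratios(X, y, c)
            if r.sum() == 0:
                warnings.warn(
                    f"ADASYN: class {c!r} region is pure (all r_i = 0); "
                    "falling back to uniform quotas", stacklevel=2)
                r = np.ones_like(r)
            from .synthdata import largest_remainder_counts
            quotas = largest_remainder_counts(need, r / r.sum())
            Xc = X[y == c]
            nn = _knn_within(Xc, self.k_neighbors)
            base = np.repeat(np.arange(len(Xc)), quotas)
            pick = rng.integers(0, self.k_neighbors, size=need)
            lam = rng.random(need)
            neigh = Xc[nn[base, pick]]
            synth = Xc[base] + lam[:, None] * (neigh - Xc[base])
            new_X.append(synth)
            new_y.append(np.full(need, c, dtype=y.dtype))
            prov.append(np.full(need, SYNTHETIC, dtype=object))
        return ResampledDataset(np.vstack(new_X), np.concatenate(new_y),
                                np.concatenate(prov).astype(str))


def enn_filter(X, y, enn_neighbors=3, target_classes=None):
    """Edited-nearest-neighbors cleaning.

    Removes every sample of the target classes for which at least
    ``ceil(enn_neighbors/2)`` (2 of 3 by default) of its nearest neighbors
    carry a different label. By default only the majority class is edited;
    other samples are never removed.

    Returns the boolean keep-mask.
    """
    X, y = _check_Xy(X, y)
    if len(y) <= enn_neighbors:
        raise ValueError("need more samples than enn_neighbors")
    counts = _class_counts(y)
    if target_classes is None:
        target_classes = [max(counts, key=counts.get)]
    order = _knn_within(X, enn_neighbors)
    disagree = (y[order] != y[:, None]).sum(axis=1)
    # Majority disagreement: >= 2 of 3 for the canonical 3-NN rule.
    threshold = int(np.ceil((enn_neighbors + 1) / 2))
    remove = np.isin(y, list(target_classes)) & (disagree >= threshold)
    return ~remove


class EditedNearestNeighbours:
    """Estimator wrapper around :func:`enn_filter`."""

    def __init__(self, n_neighbors=3, target_classes=None):
        self.n_neighbors = n_neighbors
        self.target_classes = target_classes

    def get_params(self, deep=True):
        return {"n_neighbors": self.n_neighbors,
                "target_classes": self.target_classes}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y):
        X, y = _check_Xy(X, y)
        keep = enn_filter(X, y, self.n_neighbors, self.target_classes)
        return ResampledDataset(
            X[keep], y[keep],
            np.full(int(keep.sum()), ORIGINAL, dtype=object).astype(str))


class SMOTEENN:
    """SMOTE oversampling followed by ENN cleaning of the majority class.

    The class edited by ENN is the majority class of the *original* labels
    (pre-oversampling), matching the use of ENN as a cleaner of majority
    overlap.
    """

    def __init__(self, k_neighbors=5, enn_neighbors=3, random_state=None):
        self.k_neighbors = k_neighbors
        self.enn_neighbors = enn_neighbors
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"k_neighbors": self.k_neighbors,
                "enn_neighbors": self.enn_neighbors,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y):
        X, y = _check_Xy(X, y)
        counts = _class_counts(y)
        majority = max(counts, key=counts.get)
        over = SMOTE(k_neighbors=self.k_neighbors,
                     random_state=self.random_state).fit_resample(X, y)
        keep = enn_filter(over.X, over.y, self.enn_neighbors,
                          target_classes=[majority])
        return ResampledDataset(over.X[keep], over.y[keep],
                                over.provenance[keep])


class NearMiss:
    """Distance-based undersampling of majority classes.

    Every class larger than the smallest is reduced to the smallest class's
    count. Version 1 keeps samples with the smallest mean distance to their
    ``n_neighbors`` nearest minority samples; version 2 uses the farthest
    minority samples instead; version 3 pre-selects, for each minority
    sample, its ``n_neighbors`` nearest majority samples and then keeps the
    candidates with the largest mean distance to their nearest minority
    samples.
    """

    def __init__(self, version=1, n_neighbors=3, random_state=None):
        self.version = version
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"version": self.version, "n_neighbors": self.n_neighbors,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y):
        if self.version not in (1, 2, 3):
            raise ValueError("version must be 1, 2 or 3")
        X, y = _check_Xy(X, y)
        counts = _class_counts(y)
        minority = min(counts, key=counts.get)
        n_min = counts[minority]
        if n_min < self.n_neighbors:
            raise ValueError(
                f"minority class {minority!r} has {n_min} samples, fewer "
                f"than n_neighbors={self.n_neighbors}")
        Xmin = X[y == minority]
        keep_idx = []
        for c in sorted(counts):
            idx_c = np.where(y == c)[0]
            if c == minority or counts[c] <= n_min:
                keep_idx.append(idx_c)
                continue
            d = cdist(X[idx_c], Xmin)
            d_sorted = np.sort(d, axis=1)
            if self.version == 1:
                score = d_sorted[:, : self.n_neighbors].mean(axis=1)
                order = np.argsort(score, kind="stable")
            elif self.version == 2:
                score = d_sorted[:, -self.n_neighbors:].mean(axis=1)
                order = np.argsort(score, kind="stable")
            else:
                near = np.argsort(d.T, axis=1,
                                  kind="stable")[:, : self.n_neighbors]
                candidates = np.unique(near.ravel())
                score = d_sorted[candidates,
                                 : self.n_neighbors].mean(axis=1)
                order = candidates[np.argsort(-score, kind="stable")]
                if len(order) < n_min:
                    warnings.warn(
                        "NearMiss-3: candidate pool smaller than the "
                        "minority count; keeping all candidates",
                        stacklevel=2)
            keep_idx.append(idx_c[order[:n_min]])
        keep = np.sort(np.concatenate(keep_idx))
        return ResampledDataset(
            X[keep], y[keep],
            np.full(len(keep), ORIGINAL, dtype=object).astype(str))


class RandomOverSampler:
    """Duplicate random minority rows until all classes are balanced."""

    def __init__(self, random_state=None):
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.random_state)
        counts = _class_counts(y)
        majority = max(counts.values())
        new_X, new_y = [X], [y]
        prov = [np.full(len(y), ORIGINAL, dtype=object)]
        for c in sorted(counts):
            need = majority - counts[c]
            if need <= 0:
                continue
            idx = np.where(y == c)[0]
            dup = rng.choice(idx, size=need, replace=True)
            new_X.append(X[dup])
            new_y.append(y[dup])
            prov.append(np.full(need, SYNTHETIC, dtype=object))
        return ResampledDataset(np.vstack(new_X), np.concatenate(new_y),
                                np.concatenate(prov).astype(str))


class RandomUnderSampler:
    """Keep a uniform random subset of each class at the minority count."""

    def __init__(self, random_state=None):
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y):
        X, y = _check_Xy(X, y)
        rng = np.random.default_rng(self.random_state)
        counts = _class_counts(y)
        n_min = min(counts.values())
        keep_idx = []
        for c in sorted(counts):
            idx = np.where(y == c)[0]
            if len(idx) > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep_idx.append(idx)
        keep = np.sort(np.concatenate(keep_idx))
        return ResampledDataset(
            X[keep], y[keep],
            np.full(len(keep), ORIGINAL, dtype=object).astype(str))


def class_weights(y) -> dict:
    """Inverse-frequency class weights w_c = 1 - n_c / N, mean-normalized.

    Rarer classes receive strictly larger weights; the weights are rescaled
    to mean 1 so the overall loss magnitude is unchanged.
    """
    y = np.asarray(y)
    counts = _class_counts(y)
    if len(counts) < 2:
        raise ValueError("class_weights requires at least two classes")
    n = len(y)
    raw = {c: 1.0 - cnt / n for c, cnt in counts.items()}
    mean = float(np.mean(list(raw.values())))
    return {c: w / mean for c, w in raw.items()}


def make_resampler(cfg: ResamplerConfig):
    """Instantiate the resampler described by a :class:`ResamplerConfig`.

    Returns None for methods that leave the data untouched (``none`` and
    ``weighted_loss`` — the latter acts through the training loss instead).
    """
    cfg.validate()
    m = cfg.method
    if m in ("none", "weighted_loss"):
        return None
    if m == "smote":
        return SMOTE(k_neighbors=cfg.k_neighbors, random_state=cfg.seed)
    if m == "adasyn":
        return ADASYN(k_neighbors=cfg.k_neighbors, random_state=cfg.seed)
    if m == "smoteenn":
        return SMOTEENN(k_neighbors=cfg.k_neighbors,
                        enn_neighbors=cfg.enn_neighbors,
                        random_state=cfg.seed)
    if m == "nearmiss":
        return NearMiss(version=cfg.nearmiss_version, random_state=cfg.seed)
    if m == "random_over":
        return RandomOverSampler(random_state=cfg.seed)
    if m == "random_under":
        return RandomUnderSampler(random_state=cfg.seed)
    raise ValueError(f"unknown method {m!r}")


def apply_resampling(cfg: ResamplerConfig, X, y) -> ResampledDataset:
    """Apply the configured mitigation to (X, y) — training split only."""
    sampler = make_resampler(cfg)
    if sampler is None:
        X, y = _check_Xy(X, y)
        weights = class_weights(y) if cfg.method == "weighted_loss" else None
        return ResampledDataset(
            X.copy(), y.copy(),
            np.full(len(y), ORIGINAL, dtype=object).astype(str),
            class_weights=weights)
    return sampler.fit_resample(X, y)


# Spec-style functional aliases over the estimator classes.
def smote(X, y, k=5, target_counts=None, seed=None):
    return SMOTE(k, target_counts, seed).fit_resample(X, y)


def adasyn(X, y, k=5, seed=None):
    return ADASYN(k, seed).fit_resample(X, y)


def smoteenn(X, y, cfg: ResamplerConfig | None = None):
    cfg = cfg or ResamplerConfig(method="smoteenn")
    return SMOTEENN(cfg.k_neighbors, cfg.enn_neighbors,
                    cfg.seed).fit_resample(X, y)


def nearmiss(X, y, version=1, seed=None):
    return NearMiss(version=version, random_state=seed).fit_resample(X, y)


def random_over(X, y, seed=None):
    return RandomOverSampler(seed).fit_resample(X, y)


def random_under(X, y, seed=None):
    return RandomUnderSampler(seed).fit_resample(X, y)
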