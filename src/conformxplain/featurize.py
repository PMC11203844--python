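"""Featurization: residue centers of mass, flattened 3R vectors, and
marker-distance state labels.

Each frame becomes a single vector of length 3 x n_residues (residue-major,
then x, y, z), e.g. 846 features for a 282-residue receptor. The
conformational state is read off one inter-residue distance: at or above
``active_min`` the frame is active, at or below ``inactive_max`` inactive,
otherwise intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import STATES, TrajectoryEnsemble


@dataclass
class LabelingConfig:
    """Marker-distance thresholds (Å) and the residue pair they apply to."""

    marker_pair: tuple
    active_min: float = 14.0
    inactive_max: float = 8.5

    def validate(self) -> None:
        if self.inactive_max >= self.active_min:
            raise ValueError(
                f"inactive_max={self.inactive_max} must be < "
                f"active_min={self.active_min}"
            )
        if self.inactive_max <= 0 or self.active_min <= 0:
            raise ValueError("thresholds must be positive distances in Å")


@dataclass
class LabeledFeatures:
    """n_samples x 3R feature matrix with per-sample state labels."""

    X: np.ndarray
    y: np.ndarray
    residue_table: pd.DataFrame

    @property
    def n_residues(self) -> int:
        return self.X.shape[1] // 3


def residue_center_of_mass(atom_coords, masses=None) -> np.ndarray:
    """Center of mass of a residue's atoms: sum(m_i r_i) / sum(m_i).

    With ``masses`` omitted the unweighted mean (geometric center) is
    returned.
    """
    coords = np.asarray(atom_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("atom_coords must be a non-empty list of 3D points")
    if masses is None:
        return coords.mean(axis=0)
    m = np.asarray(masses, dtype=float)
    if m.shape != (coords.shape[0],):
        raise ValueError("masses must match the number of atoms")
    if (m <= 0).any():
        raise ValueError("masses must all be positive")
    return (m[:, None] * coords).sum(axis=0) / m.sum()


def flatten_features(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Flatten frames x residues x 3 to frames x 3R (residue-major x,y,z)."""
    coords = ensemble.coordinates
    bad = ~np.isfinite(coords)
    if bad.any():
        f, r, _ = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite coordinate at frame {f}, residue {r}")
    return coords.reshape(coords.shape[0], -1)


def unflatten_features(X: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_features`."""
    X = np.asarray(X)
    if X.shape[-1] % 3:
        raise ValueError(f"feature count {X.shape[-1]} not a multiple of 3")
    return X.reshape(X.shape[0], -1, 3)


def marker_distance(frame_coords, pair) -> float:
    """Euclidean distance (Å) between two residue points of one frame."""
    coords = np.asarray(frame_coords, dtype=float)
    a, b = pair
    n = coords.shape[0]
    for i in (a, b):
        if not 0 <= i < n:
            raise IndexError(f"marker residue {i} out of range [0, {n})")
    return float(np.linalg.norm(coords[a] - coords[b]))


def assign_state(distance: float, cfg: LabelingConfig) -> str:
    """Map a marker distance to a conformational state.

    Boundaries are inclusive toward the extreme states: >= active_min is
    active, <= inactive_max is inactive, strictly between is intermediate.
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if distance >= cfg.active_min:
        return "active"
    if distance <= cfg.inactive_max:
        return "inactive"
    return "intermediate"


def assign_states(distances, cfg: LabelingConfig) -> np.ndarray:
    """Vectorized :func:`assign_state`."""
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    out = np.full(d.shape, "intermediate", dtype=object)
    out[d >= cfg.active_min] = "active"
    out[d <= cfg.inactive_max] = "inactive"
    return out.astype(str)


def label_ensemble(ensemble: TrajectoryEnsemble,
                   cfg: LabelingConfig) -> LabeledFeatures:
    """Flatten an ensemble and label every frame from its marker distance."""
    cfg.validate()
    a, b = cfg.marker_pair
    n = ensemble.n_residues
    for i in (a, b):
        if not 0 <= i < n:
            raise IndexError(f"marker residue {i} out of range [0, {n})")
    X = flatten_features(ensemble)
    dists = np.linalg.norm(
        ensemble.coordinates[:, a, :] - ensemble.coordinates[:, b, :], axis=1)
    y = assign_states(dists, cfg)
    return LabeledFeatures(X=X, y=y, residue_table=ensemble.residue_table)


__all__ = [
    "STATES", "LabelingConfig", "LabeledFeatures", "residue_center_of_mass",
    "flatten_features", "unflatten_features", "marker_distance",
    "assign_state", "assign_states", "label_ensemble",
]
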