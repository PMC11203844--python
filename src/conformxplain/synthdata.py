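"""Synthetic GPCR-like trajectory ensembles with planted ground truth.

Generates frames of per-residue 3D positions emulating the statistical
structure of receptor MD data: three conformational states (active /
intermediate / inactive) defined by a single inter-residue marker distance,
a heavily predominant intermediate class, and a small set of
state-informative residues whose positions shift between states. The
planted residues and labels are returned as ground truth so downstream
attribution methods can be scored on recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STATES = ("active", "intermediate", "inactive")

#: Receptor topology in sequence order: N-terminus, seven transmembrane
#: helices alternating with intra-/extracellular loops, C-terminus.
REGION_ORDER = (
    "N-Terminus", "H1", "ICL1", "H2", "ECL1", "H3", "ICL2", "H4",
    "ECL2", "H5", "ICL3", "H6", "ECL3", "H7", "C-Terminus",
)

# Relative segment lengths (helices long, loops short) used to apportion
# residues across the 15 segments.
_REGION_WEIGHTS = {
    "N-Terminus": 20, "H1": 32, "ICL1": 6, "H2": 30, "ECL1": 6,
    "H3": 32, "ICL2": 8, "H4": 26, "ECL2": 20, "H5": 30,
    "ICL3": 14, "H6": 32, "ECL3": 6, "H7": 30, "C-Terminus": 12,
}

#: Marker-distance sampling bands, Å: per-state (mean, sd, low, high) of a
#: truncated normal. Broad intermediate between two sharp extremes.
DEFAULT_STATE_DISTANCE_PARAMS = {
    "active": (15.5, 0.5, 14.0, np.inf),
    "intermediate": (11.0, 1.5, 8.5, 14.0),
    "inactive": (7.5, 0.5, 1e-6, 8.5),
}

DEFAULT_CLASS_PROPORTIONS = (0.10, 0.80, 0.10)


def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Apportion ``n`` items to classes by the largest-remainder rule."""
    p = np.asarray(proportions, dtype=float)
    raw = p * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def default_region_table(n_residues: int) -> pd.DataFrame:
    """Partition ``n_residues`` into contiguous receptor segments.

    Returns a residue metadata table with columns ``residue`` (0-based
    index), ``name`` and ``region``; segments appear in receptor order and
    every residue is assigned exactly once.
    """
    if n_residues < 17:
        raise ValueError(
            f"n_residues={n_residues} too small: need at least 17 residues "
            f"to place all {len(REGION_ORDER)} receptor segments"
        )
    weights = np.array([_REGION_WEIGHTS[r] for r in REGION_ORDER], float)
    counts = largest_remainder_counts(n_residues, weights / weights.sum())
    # Guarantee every segment is non-empty by borrowing from the largest.
    while (counts == 0).any():
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    regions = np.repeat(REGION_ORDER, counts)
    idx = np.arange(n_residues)
    return pd.DataFrame(
        {"residue": idx, "name": [f"RES{i}" for i in idx], "region": regions}
    )


def region_span(residue_table: pd.DataFrame, region: str) -> tuple[int, int]:
    """Return the (first, last) residue index of a contiguous region."""
    rows = residue_table.loc[residue_table["region"] == region, "residue"]
    if rows.empty:
        raise ValueError(f"region {region!r} not present in residue table")
    return int(rows.min()), int(rows.max())


def default_marker_pair(residue_table: pd.DataFrame) -> tuple[int, int]:
    """Midpoints of H3 and H6 — the analog of the R131/L272 marker pair."""
    lo3, hi3 = region_span(residue_table, "H3")
    lo6, hi6 = region_span(residue_table, "H6")
    return (lo3 + hi3) // 2, (lo6 + hi6) // 2


@dataclass
class SynthConfig:
    """Study conditions for the synthetic trajectory generator.

    Parameters
    ----------
    n_residues : int
        Number of residues; 282 mirrors the receptor construct size.
    n_frames : int
        Frames (= classification samples) to generate.
    class_proportions : tuple of float
        Fractions of (active, intermediate, inactive) frames; the default
        (0.10, 0.80, 0.10) encodes the heavy predominance of the
        intermediate state.
    marker_pair : tuple of int or None
        Residues whose distance defines the state (H3/H6 midpoints when
        None).
    state_distance_params : dict
        Per-state (mean, sd, low, high) of the truncated-normal marker
        distance in Å.
    informative_residues : dict or None
        Mapping residue index -> {state: 3-vector displacement in Å}. When
        None, ``n_informative`` residues inside H1 receive per-state random
        displacements of magnitude ``shift_magnitude``.
    n_informative, shift_magnitude : int, float
        Defaults for the planted residues (8 residues, 2.0 Å).
    noise_sd : float
        Isotropic positional noise per coordinate, Å.
    seed : int
        Master seed; identical seeds give bit-identical ensembles.
    """

    n_residues: int = 282
    n_frames: int = 600
    class_proportions: tuple = DEFAULT_CLASS_PROPORTIONS
    marker_pair: tuple | None = None
    state_distance_params: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_DISTANCE_PARAMS)
    )
    informative_residues: dict | None = None
    n_informative: int = 8
    shift_magnitude: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(
                "class_proportions must be 3 non-negative fractions summing "
                f"to 1, got {self.class_proportions}"
            )
        if self.n_residues < 17:
            raise ValueError(f"n_residues={self.n_residues} must be >= 17")
        if self.n_frames < 1:
            raise ValueError(f"n_frames={self.n_frames} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd={self.noise_sd} must be positive")
        if self.marker_pair is not None:
            a, b = self.marker_pair
            if a == b:
                raise ValueError(f"marker_pair indices must differ, got {a}")
            for i in (a, b):
                if not 0 <= i < self.n_residues:
                    raise ValueError(
                        f"marker_pair index {i} out of range "
                        f"[0, {self.n_residues})"
                    )
        for state in STATES:
            if state not in self.state_distance_params:
                raise ValueError(f"state_distance_params missing {state!r}")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic ensemble (the recovery oracle)."""

    informative_residues: set
    per_state_shift_magnitude: dict
    marker_pair: tuple
    true_labels: np.ndarray


@dataclass
class TrajectoryEnsemble:
    """frames x residues x 3 coordinate array (Å) with residue metadata."""

    coordinates: np.ndarray
    residue_table: pd.DataFrame

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coordinates.shape[1]

    def validate(self) -> None:
        if not np.isfinite(self.coordinates).all():
            raise ValueError("ensemble contains non-finite coordinates")
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must be frames x residues x 3, got shape "
                f"{self.coordinates.shape}"
            )


def _sample_truncnorm(rng, mean, sd, low, high, size):
    a = (low - mean) / sd
    b = (high - mean) / sd if np.isfinite(high) else np.inf
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _default_informative(config: SynthConfig, residue_table, marker_pair, rng):
    """Plant residues inside H1 with per-state displacement vectors.

    The intermediate state keeps the baseline geometry; active and inactive
    states displace each planted residue along distinct random directions of
    magnitude ``shift_magnitude``.
    """
    lo, hi = region_span(residue_table, "H1")
    candidates = [i for i in range(lo, hi + 1) if i not in marker_pair]
    if len(candidates) < config.n_informative:
        raise ValueError("H1 segment too small for requested planted residues")
    chosen = np.linspace(0, len(candidates) - 1, config.n_informative)
    chosen = sorted({candidates[int(round(c))] for c in chosen})
    shifts = {}
    for idx in chosen:
        per_state = {"intermediate": np.zeros(3)}
        for state in ("active", "inactive"):
            v = rng.normal(size=3)
            per_state[state] = v / np.linalg.norm(v) * config.shift_magnitude
        shifts[idx] = per_state
    return shifts


def generate_ensemble(config: SynthConfig):
    """Generate a seeded synthetic ensemble and its ground truth.

    Every frame's marker-pair distance is realized geometrically — the
    second marker residue is placed on a fixed line through the first at the
    sampled distance — so distance-based labeling reproduces the generating
    labels exactly.

    Returns
    -------
    (TrajectoryEnsemble, GroundTruth)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, F = config.n_residues, config.n_frames

    residue_table = default_region_table(R)
    marker_pair = (tuple(config.marker_pair) if config.marker_pair is not None
                   else default_marker_pair(residue_table))
    ma, mb = marker_pair

    counts = largest_remainder_counts(F, config.class_proportions)
    labels = np.repeat(STATES, counts)
    labels = labels[rng.permutation(F)]

    informative = config.informative_residues
    if informative is None:
        informative = _default_informative(config, residue_table, marker_pair,
                                           rng)
    else:
        informative = {
            int(i): {s: np.asarray(v, float) for s, v in d.items()}
            for i, d in informative.items()
        }
        for i in informative:
            if not 0 <= i < R:
                raise ValueError(f"informative residue {i} out of range")
            if i in marker_pair:
                raise ValueError(
                    f"informative residue {i} collides with marker_pair")

    # Static baseline fold: a Gaussian cloud of residue positions.
    baseline = rng.normal(0.0, 10.0, size=(R, 3))
    marker_axis = rng.normal(size=3)
    marker_axis /= np.linalg.norm(marker_axis)

    coords = baseline[None, :, :] + rng.normal(
        0.0, config.noise_sd, size=(F, R, 3))
    for idx, per_state in informative.items():
        for state in STATES:
            mask = labels == state
            coords[mask, idx, :] += per_state.get(state, np.zeros(3))

    # Marker distances: per-state truncated normals, then exact placement.
    distances = np.empty(F)
    for state in STATES:
        mask = labels == state
        mean, sd, low, high = config.state_distance_params[state]
        distances[mask] = _sample_truncnorm(rng, mean, sd, low, high,
                                            int(mask.sum()))
    coords[:, mb, :] = coords[:, ma, :] + distances[:, None] * marker_axis

    ensemble = TrajectoryEnsemble(coordinates=coords,
                                  residue_table=residue_table)
    ensemble.validate()
    truth = GroundTruth(
        informative_residues=set(informative),
        per_state_shift_magnitude={
            int(i): {s: float(np.linalg.norm(v)) for s, v in d.items()}
            for i, d in informative.items()
        },
        marker_pair=marker_pair,
        true_labels=labels,
    )
    return ensemble, truth
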