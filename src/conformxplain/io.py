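"""Plain-text file formats: trajectory/feature CSVs, contribution maps,
ground-truth and report JSON, YAML experiment configs.

Conventions: comma-separated UTF-8 with a header row, "." decimal, 0-based
residue indices, distances implicitly in Å. All numeric payloads round-trip
at double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthdata import GroundTruth, SynthConfig, TrajectoryEnsemble

TRAJECTORY_COLUMNS = ["frame", "residue", "x", "y", "z"]
RESIDUE_COLUMNS = ["residue", "name", "region"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; "
                         f"found {list(df.columns)}")


def write_trajectory_csv(ensemble: TrajectoryEnsemble, path) -> None:
    coords = ensemble.coordinates
    F, R, _ = coords.shape
    frames = np.repeat(np.arange(F), R)
    residues = np.tile(np.arange(R), F)
    flat = coords.reshape(F * R, 3)
    df = pd.DataFrame({"frame": frames, "residue": residues,
                       "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]})
    df.to_csv(path, index=False)


def read_trajectory_csv(path, residue_table=None) -> TrajectoryEnsemble:
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    frames = np.sort(df["frame"].unique())
    residues = np.sort(df["residue"].unique())
    F, R = len(frames), len(residues)
    if len(df) != F * R:
        raise ValueError(
            f"{path}: expected {F * R} rows (frames x residues), "
            f"got {len(df)}")
    df = df.sort_values(["frame", "residue"], kind="stable")
    coords = df[["x", "y", "z"]].to_numpy(float).reshape(F, R, 3)
    if residue_table is None:
        from .synthdata import default_region_table
        residue_table = default_region_table(R)
    return TrajectoryEnsemble(coordinates=coords, residue_table=residue_table)


def write_residue_table_csv(residue_table: pd.DataFrame, path) -> None:
    residue_table[RESIDUE_COLUMNS].to_csv(path, index=False)


def read_residue_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RESIDUE_COLUMNS, path)
    return df


def write_features_csv(X, y, path, provenance=None) -> None:
    X = np.asarray(X)
    cols = [f"f{j:04d}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", np.asarray(y))
    if provenance is not None:
        df.insert(1, "provenance", np.asarray(provenance))
    df.to_csv(path, index=False)


def read_features_csv(path):
    df = pd.read_csv(path)
    _require_columns(df, ["label"], path)
    feature_cols = [c for c in df.columns if c.startswith("f")]
    X = df[feature_cols].to_numpy(float)
    y = df["label"].to_numpy(str)
    prov = (df["provenance"].to_numpy(str)
            if "provenance" in df.columns else None)
    return X, y, prov


def write_contribution_map_csv(cmap, path) -> None:
    df = pd.DataFrame(cmap.values, index=list(cmap.states),
                      columns=[f"res{r}" for r in
                               range(cmap.values.shape[1])])
    df.index.name = "state"
    df.to_csv(path)


def read_contribution_map_csv(path):
    df = pd.read_csv(path, index_col="state")
    return df.index.to_list(), df.to_numpy(float)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "informative_residues": sorted(int(i) for i in
                                       truth.informative_residues),
        "per_state_shift_magnitude": truth.per_state_shift_magnitude,
        "marker_pair": list(truth.marker_pair),
        "true_labels": [str(s) for s in truth.true_labels],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        informative_residues=set(payload["informative_residues"]),
        per_state_shift_magnitude={
            int(k): v for k, v in
            payload["per_state_shift_magnitude"].items()},
        marker_pair=tuple(payload["marker_pair"]),
        true_labels=np.asarray(payload["true_labels"]))


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_yaml_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def synth_config_from_dict(d: dict) -> SynthConfig:
    known = set(SynthConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown synth config fields: {sorted(unknown)}")
    cfg = SynthConfig(**d)
    if cfg.marker_pair is not None:
        cfg.marker_pair = tuple(cfg.marker_pair)
    cfg.class_proportions = tuple(cfg.class_proportions)
    cfg.validate()
    return cfg
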