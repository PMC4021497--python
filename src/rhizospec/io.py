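"""Readers and writers for the package's plain-text interchange formats.

Tables are tab-separated with a header row; empty cells denote missing
values (e.g. a locus that failed to amplify, or lost nodule data).
Reports are JSON.  Simulation configs are flat YAML key/value files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import TABLE_COLUMNS, LinkStrengthMatrix, validate_nodule_table
from .greenhouse import GREENHOUSE_COLUMNS, validate_greenhouse_table


def read_nodule_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"plant_id": str, "nodule_id": str}
    )
    return validate_nodule_table(table)


def write_nodule_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_greenhouse_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"plant_id": str})
    return validate_greenhouse_table(table)


def write_greenhouse_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_link_matrix(matrix: LinkStrengthMatrix, counts_path, proportions_path) -> None:
    matrix.counts_frame().to_csv(counts_path, sep="\t", index_label="host_species")
    matrix.proportions_frame().to_csv(
        proportions_path, sep="\t", index_label="host_species"
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def read_config(path) -> dict:
    """Flat key/value configuration (YAML)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
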