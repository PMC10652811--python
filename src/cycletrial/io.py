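"""Serialization of assay tables, parameter sets and trajectories.

Everything round-trips through plain text: tidy CSV for tables and
trajectories, JSON for parameter fixtures and run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .assays import ASSAY_COLUMNS, GroundTruth

__all__ = [
    "read_assay_csv",
    "write_assay_csv",
    "write_truth_json",
    "read_truth_json",
    "write_trajectory_csv",
]


def write_assay_csv(table: pd.DataFrame, path) -> None:
    """Write an assay table with the canonical column order."""
    missing = [c for c in ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"assay table is missing column(s): {missing}")
    table[ASSAY_COLUMNS].to_csv(path, index=False)


def read_assay_csv(path) -> pd.DataFrame:
    """Read and validate an assay table (schema + nonnegativity)."""
    table = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {missing}")
    if (table["count"] < 0).any():
        raise ValueError(f"{path}: negative counts present")
    if (table["day"] < 0).any():
        raise ValueError(f"{path}: negative days present")
    return table[ASSAY_COLUMNS]


def write_truth_json(truth: GroundTruth, path, seed=None) -> None:
    doc = truth.to_dict()
    doc["units"] = {"doses": "nmol/L", "rates": "1/day", "time": "day"}
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_truth_json(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    doc.pop("units", None)
    doc.pop("seed", None)
    return GroundTruth.from_dict(doc)


def write_trajectory_csv(traj, path, metadata: dict | None = None) -> None:
    """Tidy trajectory CSV plus a sidecar JSON with run metadata."""
    traj.to_frame().to_csv(path, index=False)
    if metadata is not None:
        side = Path(str(path) + ".json")
        side.write_text(json.dumps(metadata, indent=2, default=str))
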