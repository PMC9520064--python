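"""File formats: HDF5 cineloops, CSV study tables and parameter reports.

Cineloop schema (version 1): a single HDF5 file with dataset ``rf``
(axial × lateral × frame) and root attributes ``schema_version``,
``pleura_depth_px``, every acquisition-geometry field and — for simulated
loops — every ground-truth motion-profile field prefixed ``gt_``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry, MotionProfile
from .parameters import ElastographyParameters, InstantaneousSeries, cumulative_curves
from .simulate import RFCineloop
from .study import STUDY_COLUMNS

SCHEMA_VERSION = 1


def save_cineloop(cineloop: RFCineloop, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=cineloop.frames)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["pleura_depth_px"] = cineloop.pleura_depth_px
        for k, v in cineloop.geometry.to_attrs().items():
            f.attrs[k] = v
        if cineloop.ground_truth is not None:
            for k, v in cineloop.ground_truth.to_attrs().items():
                f.attrs[f"gt_{k}"] = v


def load_cineloop(path: str | Path) -> RFCineloop:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported cineloop schema version {version}")
        frames = np.asarray(f["rf"])
        attrs = dict(f.attrs)
    geometry = AcquisitionGeometry.from_attrs(attrs)
    gt_attrs = {k[3:]: v for k, v in attrs.items() if k.startswith("gt_")}
    ground_truth = MotionProfile.from_attrs(gt_attrs) if gt_attrs else None
    return RFCineloop(frames=frames, geometry=geometry,
                      pleura_depth_px=int(attrs["pleura_depth_px"]),
                      ground_truth=ground_truth)


def save_study_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in STUDY_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def load_study_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_parameter_report(
    records: list[dict],
    csv_path: str | Path,
    curves: dict[str, dict[str, list[float]]] | None = None,
    json_path: str | Path | None = None,
) -> None:
    """One CSV row per cineloop (six parameters + quality metadata), with an
    optional JSON sidecar holding the full cumulative curves for plotting."""
    pd.DataFrame(records).to_csv(csv_path, index=False)
    if json_path is not None and curves is not None:
        with open(json_path, "w") as f:
            json.dump(curves, f, indent=1)


def parameters_record(params: ElastographyParameters, **metadata) -> dict:
    rec = params.as_dict()
    rec.update(metadata)
    return rec


def curves_record(series: InstantaneousSeries) -> dict[str, list[float]]:
    return {name: curve.tolist() for name, curve in cumulative_curves(series).items()}
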