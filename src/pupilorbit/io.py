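"""Plain-text interchange for ellipse datasets, contours and configs.

Datasets travel as CSV with the fixed column order
``cx,cy,semi_major,semi_minor,minor_axis_angle,label`` (angles in
degrees; label 'ideal' or 'noise').  Contours are two-column ``x,y`` CSV
files, one point per row.  Experiment configuration is a flat YAML
key-value file mirroring the dataclass fields.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from collections.abc import Sequence

import pandas as pd
import yaml

from .simulate import Contour, DatasetConfig, PupilEllipse

__all__ = [
    "write_dataset",
    "read_dataset",
    "read_contour",
    "load_dataset_config",
]

DATASET_COLUMNS = ["cx", "cy", "semi_major", "semi_minor", "minor_axis_angle", "label"]


def write_dataset(
    path: str | Path,
    ellipses: Sequence[PupilEllipse],
    labels: Sequence[str],
) -> None:
    """Write an ellipse-parameter table; one row per ellipse."""
    if len(labels) != len(ellipses):
        raise ValueError("labels must match ellipses one-to-one")
    df = pd.DataFrame(
        [
            (e.cx, e.cy, e.semi_major, e.semi_minor, e.minor_axis_angle, lab)
            for e, lab in zip(ellipses, labels)
        ],
        columns=DATASET_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> tuple[list[PupilEllipse], list[str]]:
    """Read an ellipse-parameter table written by :func:`write_dataset`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    ellipses = [
        PupilEllipse(
            float(r.cx),
            float(r.cy),
            float(r.semi_major),
            float(r.semi_minor),
            float(r.minor_axis_angle) % 180.0,
        )
        for r in df.itertuples()
    ]
    return ellipses, df["label"].astype(str).tolist()


def read_contour(path: str | Path) -> Contour:
    """Read one contour from a two-column x,y CSV file."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"x", "y"} <= set(df.columns):
        raise ValueError("contour CSV must have columns x,y")
    return Contour(df[["x", "y"]].to_numpy(dtype=float))


def load_dataset_config(path: str | Path) -> DatasetConfig:
    """Load a dataset configuration from a flat YAML key-value file.

    Unknown keys are rejected so typos fail loudly.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a key-value mapping")
    known = {f.name for f in dataclasses.fields(DatasetConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DatasetConfig(**data)
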