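"""Raster and tabular I/O: multi-page TIFF images, CSV feature tables, JSON reports.

All writers are deterministic byte-for-byte for fixed inputs: JSON keys are
sorted and floats are serialized with 17 significant digits so that CSV
round trips are exact.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelIndexError, ShapeMismatchError, ValidationError

REPORT_SCHEMA_VERSION = 1

#: float formatting guaranteeing exact binary64 round trips
FLOAT_FORMAT = "%.17g"


@dataclass
class ImageSet:
    """Named fluorescence channels of one field of view.

    ``channels`` maps a role ("protein", "marker", "nucleus") to a 2D array;
    all channels must share one shape.
    """

    channels: dict
    pixel_size_um: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ShapeMismatchError(f"channels have mixed shapes: {shapes}")
        if "protein" not in self.channels:
            raise ValidationError("ImageSet requires at least a 'protein' channel")

    @property
    def shape(self):
        return np.asarray(self.channels["protein"]).shape


def read_image(path: str, channel_map: Mapping[str, int]) -> ImageSet:
    """Read a multi-page TIFF, mapping page indices to channel roles."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    channels = {}
    for role, idx in channel_map.items():
        if idx < 0 or idx >= pages.shape[0]:
            raise ChannelIndexError(
                f"channel map requests page {idx} but {path} has {pages.shape[0]} pages"
            )
        channels[role] = np.asarray(pages[idx])
    return ImageSet(channels=channels, source_path=str(path))


def write_image(image_set: ImageSet, path: str,
                order: Sequence[str] = ("protein", "marker", "nucleus"),
                dtype=np.uint16) -> list[str]:
    """Write channels as TIFF pages (those present, in ``order``); returns roles written."""
    roles = [r for r in order if r in image_set.channels]
    stack = np.stack(
        [_to_dtype(image_set.channels[r], dtype) for r in roles]
    )
    tifffile.imwrite(path, stack)
    return roles


def write_mask(labels: np.ndarray, path: str) -> None:
    """Write a label mask as a single-page 16-bit TIFF."""
    arr = np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("too many labels for a 16-bit mask")
    tifffile.imwrite(path, arr.astype(np.uint16))


def read_mask(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return tifffile.imread(path).astype(np.int32)


def _to_dtype(arr: np.ndarray, dtype) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(np.rint(arr), info.min, info.max).astype(dtype)
    return arr.astype(dtype)


@dataclass
class FeatureTable:
    """Per-cell feature matrix with optional class labels.

    ``values`` is ``n_cells x n_features``; ``feature_names`` fixes the
    column order; ``class_labels`` is None for unlabelled data.
    """

    cell_ids: list
    feature_names: list
    values: np.ndarray
    class_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2D array")
        if self.values.shape != (len(self.cell_ids), len(self.feature_names)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.feature_names)} features"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell_id in feature table")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")
        if self.class_labels is not None and len(self.class_labels) != len(self.cell_ids):
            raise ValidationError("class_labels length mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "class_label",
                  self.class_labels if self.class_labels is not None else "")
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            cell_ids=list(self.cell_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            class_labels=None if self.class_labels is None else list(self.class_labels),
        )


def write_feature_table(table: FeatureTable, path: str) -> None:
    """Write ``cell_id,class_label,<features...>`` CSV at full float precision."""
    table.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT,
                            lineterminator="\n")


def read_feature_table(path: str) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "cell_id" or df.columns[1] != "class_label":
        raise ValidationError(
            "feature CSV must start with cell_id,class_label columns"
        )
    labels = df["class_label"]
    has_labels = len(df) > 0 and not (labels.isna().all() or (labels == "").all())
    return FeatureTable(
        cell_ids=df["cell_id"].tolist(),
        feature_names=list(df.columns[2:]),
        values=df.iloc[:, 2:].to_numpy(dtype=np.float64)
        if len(df) else np.zeros((0, len(df.columns) - 2)),
        class_labels=labels.astype(str).tolist() if has_labels else None,
    )


def write_ground_truth(truths, path: str) -> None:
    """CSV with header ``cell_id,class_label,coloc_fraction``."""
    df = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truths],
            "class_label": [t.class_label for t in truths],
            "coloc_fraction": [t.coloc_fraction_used for t in truths],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str) -> None:
    """Write a cluster report as versioned, key-sorted JSON."""
    payload = _jsonify(dict(report))
    payload.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
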