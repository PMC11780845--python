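"""File formats: JSON annotations, 16-bit label TIFFs, feature/score CSVs.

Everything is plain text or standard imagery: PNG/TIFF for images, JSON for
annotations, benchmarks and configs (masks as row-major run-length encoding),
CSV for feature and score tables.  All writers round-trip losslessly through
their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detect import SuspiciousPoint
from .morphometry import FeatureVector
from .scoring import ReferenceBenchmark
from .simulate import GroundTruthObject
from .stains import StainMethod

FEATURE_COLUMNS = ("id", "stain", *FeatureVector.PARAMETERS, "in_ecm", "label")
REQUIRED_FEATURE_COLUMNS = ("id", "stain", *FeatureVector.PARAMETERS)


class SchemaError(ValueError):
    """A file violated the expected schema; the message names the field."""


# ---------------------------------------------------------------------------
# masks as run-length encoding


def mask_to_rle(mask: np.ndarray) -> list[int]:
    """Row-major RLE of a boolean mask: [start, length, start, length, ...]."""
    flat = np.asarray(mask, dtype=bool).ravel()
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, stops = edges[::2], edges[1::2]
    out = np.empty(2 * len(starts), dtype=int)
    out[::2] = starts
    out[1::2] = stops - starts
    return out.tolist()


def rle_to_mask(rle: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in zip(rle[::2], rle[1::2]):
        flat[start : start + length] = True
    return flat.reshape(shape)


# ---------------------------------------------------------------------------
# annotations (ground truth and detections share one schema)


def _object_record(obj) -> dict:
    record = {
        "bbox": [int(v) for v in obj.bbox],
        "mask_rle": mask_to_rle(obj.mask),
        "mask_shape": [int(s) for s in obj.mask.shape],
        "centroid": [float(c) for c in obj.centroid],
    }
    if isinstance(obj, GroundTruthObject):
        record["label"] = obj.class_label
        record["params"] = {k: float(v) for k, v in obj.params.items()}
        record["in_ecm"] = bool(obj.in_ecm)
    else:
        record["id"] = int(obj.id)
        record["stain"] = obj.stain.value
        record["in_ecm"] = None if obj.in_ecm is None else bool(obj.in_ecm)
    return record


def write_annotations(path, objects, image_shape=None) -> None:
    """Write ground-truth objects or detected points as a JSON annotation file."""
    data = {
        "schema": "decmscore-annotations-v1",
        "image_shape": None if image_shape is None else [int(s) for s in image_shape],
        "objects": [_object_record(o) for o in objects],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_annotations(path) -> list:
    """Read an annotation file back into GroundTruthObject / SuspiciousPoint lists."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("schema") != "decmscore-annotations-v1":
        raise SchemaError(f"{path}: missing or unknown 'schema' field")
    out = []
    for i, rec in enumerate(data.get("objects", [])):
        for key in ("bbox", "mask_rle", "mask_shape"):
            if key not in rec:
                raise SchemaError(f"{path}: object {i} lacks required field {key!r}")
        mask = rle_to_mask(rec["mask_rle"], tuple(rec["mask_shape"]))
        bbox = tuple(rec["bbox"])
        centroid = tuple(rec.get("centroid", (0.0, 0.0)))
        if "id" in rec:
            out.append(SuspiciousPoint(id=rec["id"], bbox=bbox, mask=mask,
                                       stain=StainMethod.parse(rec["stain"]),
                                       centroid=centroid, in_ecm=rec.get("in_ecm")))
        else:
            out.append(GroundTruthObject(class_label=rec["label"], bbox=bbox,
                                         mask=mask, centroid=centroid,
                                         params=rec.get("params", {}),
                                         in_ecm=rec.get("in_ecm", False)))
    return out


def write_label_image(path, objects, shape) -> None:
    """16-bit label TIFF: background 0, object k at value k+1 (raster id order)."""
    label = np.zeros(shape, dtype=np.uint16)
    for k, obj in enumerate(objects, start=1):
        rr, cc = obj.pixel_coords()
        label[rr, cc] = k
    tifffile.imwrite(path, label)


# ---------------------------------------------------------------------------
# images


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


# ---------------------------------------------------------------------------
# feature tables


def features_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Normalize a list of feature records into the canonical CSV layout."""
    frame = pd.DataFrame(rows)
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature table lacks required columns: {missing}")
    for col in ("in_ecm", "label"):
        if col not in frame.columns:
            frame[col] = None
    return frame[list(FEATURE_COLUMNS)]


def write_features(path, frame: pd.DataFrame) -> None:
    features_to_frame(frame.to_dict("records")).to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {missing}; "
            f"required: {list(REQUIRED_FEATURE_COLUMNS)}")
    return frame


def frame_to_feature_vectors(frame: pd.DataFrame) -> list[FeatureVector]:
    return [FeatureVector(**{p: float(row[p]) for p in FeatureVector.PARAMETERS})
            for _, row in frame.iterrows()]


# ---------------------------------------------------------------------------
# benchmarks


def benchmark_to_dict(bench: ReferenceBenchmark) -> dict:
    return {
        "schema": "decmscore-benchmark-v1",
        "stain": bench.stain.value,
        "nucleus_type": bench.nucleus_type,
        "means": bench.means,
        "sds": bench.sds,
        "n": bench.n,
    }


def write_benchmark(path, bench: ReferenceBenchmark) -> None:
    with open(path, "w") as fh:
        json.dump(benchmark_to_dict(bench), fh, indent=1)


def read_benchmark(path) -> ReferenceBenchmark:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("stain", "nucleus_type", "means", "sds", "n"):
        if key not in data:
            raise SchemaError(f"{path}: benchmark lacks required field {key!r}")
    missing = [p for p in FeatureVector.PARAMETERS if p not in data["means"]]
    if missing:
        raise SchemaError(f"{path}: benchmark means lack parameters {missing}")
    return ReferenceBenchmark(stain=StainMethod.parse(data["stain"]),
                              nucleus_type=data["nucleus_type"],
                              means={k: float(v) for k, v in data["means"].items()},
                              sds={k: float(v) for k, v in data["sds"].items()},
                              n=int(data["n"]))
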