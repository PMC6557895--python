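"""Readers and writers for all artifact file formats.

Populations travel as CSV (header ``experiment_id,subject_id,replicate,
generation,member,d_0,...,d_10``; floats at 17 significant digits so
round trips are lossless), landmarks as JSON with an explicit frame
field, schemas as YAML, and metric contexts / run metadata as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import MetricContext
from .schema import (
    DISTANCE_COLUMNS,
    DistanceDef,
    DistanceSchema,
    FACE_FRAME,
    FaceVector,
    LandmarkSet,
    PIXEL_FRAME,
    default_schema,
)

__all__ = [
    "read_population_csv",
    "write_population_csv",
    "read_landmarks_json",
    "write_landmarks_json",
    "read_schema_yaml",
    "write_schema_yaml",
    "read_metric_context",
    "write_metric_context",
    "read_image",
    "write_image",
    "pixel_to_face_frame",
    "face_to_pixel_frame",
]

POPULATION_COLUMNS = [
    "experiment_id",
    "subject_id",
    "replicate",
    "generation",
    "member",
    *DISTANCE_COLUMNS,
]


def read_population_csv(
    path, schema: DistanceSchema | None = None, strict: bool = False
) -> pd.DataFrame:
    """Load a population table, checking header and the h = 1 constraint."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population CSV {path}: missing column(s) {missing}")
    d = df[DISTANCE_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError(f"population CSV {path}: non-numeric distance fields")
    schema = schema or default_schema()
    h = d[:, sorted(schema.constraint_indices)].sum(axis=1)
    bad = np.abs(h - 1.0) > 1e-6
    if bad.any():
        msg = f"population CSV {path}: {bad.sum()} row(s) violate the h=1 constraint"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    return df[POPULATION_COLUMNS]


def write_population_csv(records: pd.DataFrame, path) -> None:
    records[POPULATION_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_landmarks_json(path, schema: DistanceSchema | None = None) -> LandmarkSet:
    with open(path) as fh:
        data = json.load(fh)
    if "frame" not in data:
        raise ValueError(f"{path}: landmark file must declare a 'frame'")
    valid = set((schema or default_schema()).landmark_ids)
    pos = {}
    for rec in data["landmarks"]:
        if rec["id"] not in valid:
            raise ValueError(
                f"{path}: unknown landmark id {rec['id']!r}; valid ids: {sorted(valid)}"
            )
        pos[rec["id"]] = (float(rec["x"]), float(rec["y"]))
    return LandmarkSet(pos, frame=data["frame"], pixel_scale=data.get("pixel_scale"))


def write_landmarks_json(L: LandmarkSet, path) -> None:
    data = {
        "frame": L.frame,
        "pixel_scale": L.pixel_scale,
        "landmarks": [
            {"id": k, "x": x, "y": y} for k, (x, y) in L.positions.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def pixel_to_face_frame(L: LandmarkSet) -> LandmarkSet:
    """Affine frame change: midline x -> 0, top y -> 0, chin y -> 1."""
    if L.frame != PIXEL_FRAME:
        raise ValueError("expected pixel-frame landmarks")
    top, chin = np.array(L["top"]), np.array(L["chin"])
    length = chin[1] - top[1]
    if length <= 0:
        raise ValueError("non-positive face height")
    mid_x = 0.5 * (top[0] + chin[0])
    pos = {
        k: ((x - mid_x) / length, (y - top[1]) / length)
        for k, (x, y) in L.positions.items()
    }
    return LandmarkSet(pos, frame=FACE_FRAME, pixel_scale=float(length))


def face_to_pixel_frame(
    L: LandmarkSet, length_px: float, top_xy: tuple[float, float]
) -> LandmarkSet:
    if L.frame != FACE_FRAME:
        raise ValueError("expected face-frame landmarks")
    mx, ty = top_xy
    pos = {
        k: (mx + x * length_px, ty + y * length_px)
        for k, (x, y) in L.positions.items()
    }
    return LandmarkSet(pos, frame=PIXEL_FRAME, pixel_scale=float(length_px))


# --- schema YAML ------------------------------------------------------------

def write_schema_yaml(schema: DistanceSchema, path) -> None:
    data = {
        "landmark_ids": list(schema.landmark_ids),
        "symmetry": dict(schema.symmetry),
        "distance_defs": [
            {"index": d.index, "alpha": d.alpha, "beta": d.beta, "axis": d.axis}
            for d in schema.distance_defs
        ],
        "constraint_indices": sorted(schema.constraint_indices),
        "free_landmarks": list(schema.free_landmarks),
        "reference": schema.reference.tolist(),
        "lo": schema.lo.tolist(),
        "hi": schema.hi.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_schema_yaml(path) -> DistanceSchema:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DistanceSchema(
        landmark_ids=tuple(data["landmark_ids"]),
        symmetry=data["symmetry"],
        distance_defs=tuple(
            DistanceDef(d["index"], d["alpha"], d["beta"], d["axis"])
            for d in data["distance_defs"]
        ),
        constraint_indices=frozenset(data["constraint_indices"]),
        free_landmarks=tuple(data["free_landmarks"]),
        reference=np.array(data["reference"], dtype=float),
        lo=np.array(data["lo"], dtype=float),
        hi=np.array(data["hi"], dtype=float),
    )


def write_metric_context(ctx: MetricContext, path) -> None:
    with open(path, "w") as fh:
        json.dump(ctx.to_dict(), fh)


def read_metric_context(path) -> MetricContext:
    with open(path) as fh:
        return MetricContext.from_dict(json.load(fh))


# --- images -----------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Load a PNG/JPEG as a float grayscale array (color converted)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def write_image(img: np.ndarray, path) -> None:
    from PIL import Image

    arr = np.clip(np.asarray(img), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
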