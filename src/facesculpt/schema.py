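"""Geometric face-space: landmarks, inter-landmark distances, and conversions.

A face is parametrized by D = 11 vertical/horizontal inter-landmark
distances ``d_0 .. d_10``, expressed as proportions of the total facial
length.  The four vertical segments ``d_1 .. d_4`` partition the face
height from the top landmark to the chin, so they carry the normalization
constraint ``h = d_1 + d_2 + d_3 + d_4 = 1`` that fixes the intrinsic
scale invariance of the problem.  Equivalently a face is a set of 10
non-redundant Cartesian coordinates of 7 landmarks; both parametrizations
are interconvertible here.

Frame convention: in the *face frame* x points rightward from the facial
midline and y points *downward* from the top landmark (image convention),
so a "higher" facial feature has a *smaller* y.  The top landmark sits at
y = 0 and the chin at y = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DistanceDef",
    "DistanceSchema",
    "FaceVector",
    "LandmarkSet",
    "StandardizedDataset",
    "default_schema",
    "project_to_constraint",
    "distances_to_landmarks",
    "landmarks_to_distances",
    "cartesian_coordinates",
    "cartesian_to_distances",
    "standardize",
    "N_DISTANCES",
]

N_DISTANCES = 11

VERTICAL = "vertical"
HORIZONTAL = "horizontal"


@dataclass(frozen=True)
class DistanceDef:
    """One inter-landmark distance: ``d_i = |c_alpha - c_beta|`` along an axis."""

    index: int
    alpha: str
    beta: str
    axis: str  # "vertical" (y) or "horizontal" (x)

    def __post_init__(self) -> None:
        if self.axis not in (VERTICAL, HORIZONTAL):
            raise ValueError(f"axis must be vertical|horizontal, got {self.axis!r}")


@dataclass(frozen=True)
class DistanceSchema:
    """Landmark roster plus the 11 distance definitions and their bounds.

    The schema is a plain data object: an alternative landmark/distance
    pairing is a configuration change, not a code change.
    """

    landmark_ids: tuple[str, ...]
    symmetry: Mapping[str, str]  # lateral landmark <-> mirror; midline self-paired
    distance_defs: tuple[DistanceDef, ...]
    constraint_indices: frozenset[int]
    free_landmarks: tuple[str, ...]
    reference: np.ndarray  # anatomically plausible default d, shape (11,)
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        if len(self.distance_defs) != N_DISTANCES:
            raise ValueError("schema must define exactly 11 distances")
        idx = sorted(d.index for d in self.distance_defs)
        if idx != list(range(N_DISTANCES)):
            raise ValueError("distance indices must be 0..10 and unique")
        ids = set(self.landmark_ids)
        for d in self.distance_defs:
            if d.alpha not in ids or d.beta not in ids:
                raise ValueError(f"d_{d.index} references unknown landmark")
        for i in self.constraint_indices:
            if self.def_by_index(i).axis != VERTICAL:
                raise ValueError("constraint indices must refer to vertical distances")
        for a, b in self.symmetry.items():
            if self.symmetry.get(b) != a:
                raise ValueError("symmetry map must be an involution")

    def def_by_index(self, i: int) -> DistanceDef:
        for d in self.distance_defs:
            if d.index == i:
                return d
        raise KeyError(i)

    @property
    def constraint_mask(self) -> np.ndarray:
        m = np.zeros(N_DISTANCES, dtype=bool)
        m[list(self.constraint_indices)] = True
        return m


@dataclass(frozen=True)
class FaceVector:
    """11 inter-landmark distances in facial-length units, h = Σ_{i=1..4} d_i = 1."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (N_DISTANCES,):
            raise ValueError(f"FaceVector needs {N_DISTANCES} distances, got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distance")
        if np.any(d < 0):
            raise ValueError("negative distance")

    def constraint_sum(self, schema: "DistanceSchema") -> float:
        return float(self.d[schema.constraint_mask].sum())

    def validate(self, schema: "DistanceSchema", atol: float = 1e-9) -> "FaceVector":
        if abs(self.constraint_sum(schema) - 1.0) > atol:
            raise ValueError("constraint sum != 1")
        if np.any(self.d < schema.lo - atol) or np.any(self.d > schema.hi + atol):
            raise ValueError("distance out of bounds")
        return self

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, FaceVector):
            return NotImplemented
        return bool(np.array_equal(self.d, other.d))

    def __hash__(self) -> int:
        return hash(self.d.tobytes())


FACE_FRAME = "face"
PIXEL_FRAME = "pixel"


@dataclass
class LandmarkSet:
    """Named 2D landmark positions in the face or pixel frame."""

    positions: dict[str, tuple[float, float]]
    frame: str = FACE_FRAME
    pixel_scale: float | None = None  # pixels per facial length (pixel frame only)

    def __post_init__(self) -> None:
        if self.frame not in (FACE_FRAME, PIXEL_FRAME):
            raise ValueError(f"unknown frame {self.frame!r}")

    def __getitem__(self, key: str) -> tuple[float, float]:
        return self.positions[key]

    def ids(self) -> list[str]:
        return list(self.positions)

    def as_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.ids()
        return np.array([self.positions[k] for k in order], dtype=float)


# --- default schema -------------------------------------------------------

MIDLINE = ("top", "nose_end", "mouth_center", "chin")

_LATERAL_PAIRS = (
    ("zygomatic_l", "zygomatic_r"),
    ("eye_center_l", "eye_center_r"),
    ("eye_inner_l", "eye_inner_r"),
    ("eye_outer_l", "eye_outer_r"),
    ("nose_wing_l", "nose_wing_r"),
    ("mouth_corner_l", "mouth_corner_r"),
    ("jaw_l", "jaw_r"),
)

#: anatomically plausible reference distances (proportions of face length)
_REFERENCE = np.array(
    [0.10,  # d_0  eye line -> zygomatic (vertical offset)
     0.30,  # d_1  top -> eye line
     0.30,  # d_2  eye line -> nose end (nose length)
     0.12,  # d_3  nose end -> mouth line
     0.28,  # d_4  mouth line -> chin
     0.75,  # d_5  face (zygomatic) width
     0.32,  # d_6  inter-eye (pupil) distance
     0.28,  # d_7  mouth width
     0.12,  # d_8  eye width (inner -> outer corner)
     0.20,  # d_9  nose width
     0.55,  # d_10 jaw width
     ])


def default_schema() -> DistanceSchema:
    """The shipped 18-landmark, 11-distance face-space schema.

    d_1..d_4 are the vertical segments partitioning total face height
    (hence the h = 1 constraint); d_0 is the vertical eye-line→zygomatic
    offset; d_5..d_10 are the six bilateral widths.
    """
    landmark_ids = MIDLINE + tuple(l for pair in _LATERAL_PAIRS for l in pair)
    symmetry: dict[str, str] = {m: m for m in MIDLINE}
    for a, b in _LATERAL_PAIRS:
        symmetry[a] = b
        symmetry[b] = a
    defs = (
        DistanceDef(0, "eye_center_l", "zygomatic_l", VERTICAL),
        DistanceDef(1, "top", "eye_center_l", VERTICAL),
        DistanceDef(2, "eye_center_l", "nose_end", VERTICAL),
        DistanceDef(3, "nose_end", "mouth_center", VERTICAL),
        DistanceDef(4, "mouth_center", "chin", VERTICAL),
        DistanceDef(5, "zygomatic_l", "zygomatic_r", HORIZONTAL),
        DistanceDef(6, "eye_center_l", "eye_center_r", HORIZONTAL),
        DistanceDef(7, "mouth_corner_l", "mouth_corner_r", HORIZONTAL),
        DistanceDef(8, "eye_inner_l", "eye_outer_l", HORIZONTAL),
        DistanceDef(9, "nose_wing_l", "nose_wing_r", HORIZONTAL),
        DistanceDef(10, "jaw_l", "jaw_r", HORIZONTAL),
    )
    free = (
        "nose_end",
        "zygomatic_l",
        "eye_center_l",
        "eye_outer_l",
        "nose_wing_l",
        "mouth_corner_l",
        "jaw_l",
    )
    return DistanceSchema(
        landmark_ids=landmark_ids,
        symmetry=symmetry,
        distance_defs=defs,
        constraint_indices=frozenset({1, 2, 3, 4}),
        free_landmarks=free,
        reference=_REFERENCE.copy(),
        lo=0.5 * _REFERENCE,
        hi=1.5 * _REFERENCE,
    )


# --- operations -----------------------------------------------------------

def project_to_constraint(
    raw: np.ndarray | FaceVector,
    schema: DistanceSchema,
    *,
    atol: float = 1e-9,
    max_iter: int = 100,
) -> FaceVector:
    """Map arbitrary finite raw distances to a valid :class:`FaceVector`.

    The four constraint coordinates are rescaled by ``1/h`` so their sum is
    one, all coordinates are clamped to the schema bounds, and the two
    steps are iterated to joint feasibility.  The rescale preserves the
    proportions among the vertical segments and the map is idempotent on
    already-valid vectors.
    """
    d = np.asarray(raw.d if isinstance(raw, FaceVector) else raw, dtype=float).copy()
    if d.shape != (N_DISTANCES,):
        raise ValueError("raw must have 11 entries")
    if not np.all(np.isfinite(d)):
        raise ValueError("raw distances must be finite")
    mask = schema.constraint_mask
    if np.sum(schema.lo[mask]) > 1.0 + atol or np.sum(schema.hi[mask]) < 1.0 - atol:
        raise ValueError("bounds make the h = 1 constraint unreachable")
    d[~mask] = np.clip(d[~mask], schema.lo[~mask], schema.hi[~mask])
    for _ in range(max_iter):
        h = d[mask].sum()
        if h <= 0:
            raise ValueError("non-positive constraint sum; infeasible input")
        if abs(h - 1.0) > 1e-15:
            d[mask] /= h
        clamped = np.clip(d[mask], schema.lo[mask], schema.hi[mask])
        if np.array_equal(clamped, d[mask]):
            break
        d[mask] = clamped
    else:
        raise ValueError("constraint projection did not converge")
    if abs(d[mask].sum() - 1.0) > atol:
        raise ValueError("bounds make the h = 1 constraint unreachable")
    return FaceVector(d)


def _face_positions(d: np.ndarray) -> dict[str, tuple[float, float]]:
    """Face-frame landmark positions under the default landmark roster."""
    y_eye = d[1]
    y_nose = d[1] + d[2]
    y_mouth = d[1] + d[2] + d[3]
    y_chin = y_mouth + d[4]
    y_zyg = y_eye + d[0]
    y_jaw = 0.5 * (y_mouth + y_chin)
    pos: dict[str, tuple[float, float]] = {
        "top": (0.0, 0.0),
        "nose_end": (0.0, y_nose),
        "mouth_center": (0.0, y_mouth),
        "chin": (0.0, y_chin),
    }

    def lateral(stem: str, half_x: float, y: float) -> None:
        pos[stem + "_l"] = (-half_x, y)
        pos[stem + "_r"] = (+half_x, y)

    lateral("zygomatic", d[5] / 2, y_zyg)
    lateral("eye_center", d[6] / 2, y_eye)
    lateral("eye_inner", d[6] / 2 - d[8] / 2, y_eye)
    lateral("eye_outer", d[6] / 2 + d[8] / 2, y_eye)
    lateral("nose_wing", d[9] / 2, y_nose)
    lateral("mouth_corner", d[7] / 2, y_mouth)
    lateral("jaw", d[10] / 2, y_jaw)
    return pos


def distances_to_landmarks(d: FaceVector, schema: DistanceSchema) -> LandmarkSet:
    """Place the 18 landmarks in the face frame from an 11-distance vector.

    Vertical positions accumulate d_1..d_4 downward from the top landmark;
    each bilateral pair is split symmetrically about the midline x = 0.
    """
    pos = _face_positions(d.d)
    missing = set(schema.landmark_ids) - set(pos)
    if missing:
        raise ValueError(f"schema landmarks without placement rule: {sorted(missing)}")
    return LandmarkSet({k: pos[k] for k in schema.landmark_ids}, frame=FACE_FRAME)


def landmarks_to_distances(L: LandmarkSet, schema: DistanceSchema) -> FaceVector:
    """Measure the 11 distances off a landmark set, in facial-length units.

    Scale invariant (everything is divided by the top→chin height) and
    mirror invariant (absolute coordinate differences).  Works in either
    frame; in the pixel frame y still increases downward.
    """
    height = abs(L["chin"][1] - L["top"][1])
    if height <= 0:
        raise ValueError("zero face height")
    d = np.empty(N_DISTANCES)
    for dd in schema.distance_defs:
        a, b = L[dd.alpha], L[dd.beta]
        k = 1 if dd.axis == VERTICAL else 0
        d[dd.index] = abs(a[k] - b[k]) / height
    return FaceVector(d)


#: the 10 non-redundant Cartesian coordinates, as (landmark, axis) pairs.
#: Omitted: top (frame origin), nose_end.x (midline), eye_outer.y /
#: nose_wing.y / jaw.y (tied to the eye, nose and jaw lines).
FREE_COORDINATES: tuple[tuple[str, int], ...] = (
    ("eye_center_l", 0),
    ("eye_center_l", 1),
    ("zygomatic_l", 0),
    ("zygomatic_l", 1),
    ("nose_end", 1),
    ("eye_outer_l", 0),
    ("nose_wing_l", 0),
    ("mouth_corner_l", 0),
    ("mouth_corner_l", 1),
    ("jaw_l", 0),
)


def cartesian_coordinates(d: FaceVector, schema: DistanceSchema) -> np.ndarray:
    """The 10 non-redundant face-frame Cartesian coordinates of a face.

    The constraint h = 1 removes one of the 11 distance degrees of
    freedom, so the constrained face-space is 10-dimensional; this is its
    Cartesian chart.  Invertible via :func:`cartesian_to_distances`.
    """
    L = distances_to_landmarks(d, schema)
    return np.array([L[lm][ax] for lm, ax in FREE_COORDINATES])


def cartesian_to_distances(c: np.ndarray, schema: DistanceSchema) -> FaceVector:
    """Inverse of :func:`cartesian_coordinates`."""
    c = np.asarray(c, dtype=float)
    if c.shape != (10,):
        raise ValueError("expected 10 Cartesian coordinates")
    (ec_x, ec_y, zy_x, zy_y, ne_y, eo_x, nw_x, mc_x, mc_y, jw_x) = c
    d = np.empty(N_DISTANCES)
    d[1] = ec_y
    d[0] = zy_y - ec_y
    d[2] = ne_y - ec_y
    d[3] = mc_y - ne_y
    d[4] = 1.0 - (d[1] + d[2] + d[3])
    d[5] = 2 * abs(zy_x)
    d[6] = 2 * abs(ec_x)
    d[7] = 2 * abs(mc_x)
    d[8] = 2 * (abs(eo_x) - abs(ec_x))
    d[9] = 2 * abs(nw_x)
    d[10] = 2 * abs(jw_x)
    return FaceVector(d)


# --- standardized datasets ------------------------------------------------

@dataclass
class StandardizedDataset:
    """Facial vectors with per-coordinate standardized fluctuations.

    ``y_i = (f_i - <f_i>) / sigma_i`` with the mean and sd taken over a
    designated reference subset (sd uses the n-1 denominator).
    """

    records: "object"  # pandas.DataFrame with meta columns + d_0..d_10
    mean: np.ndarray
    sigma: np.ndarray
    y: np.ndarray  # shape (n_records, 11)

    META_COLUMNS = ("experiment_id", "subject_id", "replicate", "generation", "member")

    def subject_groups(self) -> dict[object, np.ndarray]:
        """Row indices grouped by subject_id."""
        import pandas as pd  # local: keep schema importable without pandas

        g = self.records.groupby("subject_id", sort=True).indices
        return {k: np.asarray(v) for k, v in g.items()}


DISTANCE_COLUMNS = [f"d_{i}" for i in range(N_DISTANCES)]


def standardize(records, reference_index: Iterable[int] | None = None) -> StandardizedDataset:
    """Standardize the distance columns of a population table.

    Parameters
    ----------
    records : pandas.DataFrame
        Must carry the columns ``d_0 .. d_10`` (facial-length units).
    reference_index : optional
        Positional row indices of the reference subset used to fit the
        mean and sd; defaults to all rows.
    """
    f = records[DISTANCE_COLUMNS].to_numpy(dtype=float)
    ref = f if reference_index is None else f[np.asarray(list(reference_index))]
    if ref.shape[0] < 2:
        raise ValueError("reference subset needs at least 2 records")
    mean = ref.mean(axis=0)
    sigma = ref.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        bad = [DISTANCE_COLUMNS[i] for i in np.where(sigma <= 0)[0]]
        raise ValueError(f"zero-variance coordinate(s): {bad}")
    y = (f - mean) / sigma
    return StandardizedDataset(records=records, mean=mean, sigma=sigma, y=y)
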