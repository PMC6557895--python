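"""Landmark-driven image deformation in the similarity class.

The deformation is a moving-least-squares (MLS) map: around every point
``v`` the control-point displacements are fitted, with weights
``w_a = |p_a - v|^(-2*alpha)``, by the best *similarity* transform
(rotation + uniform scale + translation).  Restricting the local fit to
the similarity class — rather than general affine — is what keeps warped
faces looking realistic: local shapes are rotated and scaled but never
sheared.

For speed the map is evaluated only at the vertices of a coarse grid
(spacing <= 15 px); every grid cell is then split into two triangles and
each destination triangle is filled by inverse-affine bilinear sampling
of its source triangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import (
    DistanceSchema,
    FaceVector,
    LandmarkSet,
    PIXEL_FRAME,
    distances_to_landmarks,
)

__all__ = [
    "ControlPointPairs",
    "local_similarity",
    "make_warp_grid",
    "deform_image",
    "render_face",
    "face_to_pixel_landmarks",
]

MAX_GRID_PX = 15


@dataclass
class ControlPointPairs:
    """Paired source/target control points in the pixel frame."""

    source: np.ndarray  # (n, 2) as (x, y)
    target: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValueError("source/target must be matching (n, 2) arrays")
        if len(self.source) < 3:
            raise ValueError("need at least 3 control points")
        # non-collinearity: rank of centered source must be 2
        c = self.source - self.source.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-9) < 2:
            raise ValueError("control points are collinear")

    @classmethod
    def from_landmarks(cls, src: LandmarkSet, dst: LandmarkSet) -> "ControlPointPairs":
        ids = tuple(sorted(set(src.ids()) & set(dst.ids())))
        return cls(src.as_array(ids), dst.as_array(ids), ids=ids)


def local_similarity(
    v: np.ndarray, cp: ControlPointPairs, alpha: float = 1.0
) -> np.ndarray:
    """Evaluate the MLS similarity deformation at point(s) ``v``.

    Supports a single (2,) point or an (m, 2) batch.  Points coinciding
    with a source control point map exactly to the paired target.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = np.atleast_2d(v)  # (m, 2)
    p, q = cp.source, cp.target  # (n, 2)

    diff = V[:, None, :] - p[None, :, :]  # (m, n, 2)
    d2 = np.einsum("mni,mni->mn", diff, diff)  # squared distances
    hit = d2 < 1e-18  # v on a control point
    d2safe = np.where(hit, 1.0, d2)
    w = d2safe ** (-alpha)  # (m, n)
    wsum = w.sum(axis=1, keepdims=True)

    pstar = (w[:, :, None] * p[None, :, :]).sum(axis=1) / wsum  # (m, 2)
    qstar = (w[:, :, None] * q[None, :, :]).sum(axis=1) / wsum
    phat = p[None, :, :] - pstar[:, None, :]  # (m, n, 2)
    qhat = q[None, :, :] - qstar[:, None, :]

    mu = np.einsum("mn,mni,mni->m", w, phat, phat)  # (m,)
    if np.any(mu <= 0):
        raise ValueError("degenerate control-point geometry (mu_s = 0)")
    # similarity matrix M = [[a, -b], [b, a]]
    a = np.einsum("mn,mni,mni->m", w, phat, qhat) / mu
    perp = np.stack([-phat[..., 1], phat[..., 0]], axis=-1)  # rotate +90 deg
    b = np.einsum("mn,mni,mni->m", w, perp, qhat) / mu

    rel = V - pstar
    out = np.empty_like(V)
    out[:, 0] = rel[:, 0] * a - rel[:, 1] * b + qstar[:, 0]
    out[:, 1] = rel[:, 0] * b + rel[:, 1] * a + qstar[:, 1]

    if np.any(hit):
        m_idx, n_idx = np.where(hit)
        out[m_idx] = q[n_idx]
    return out[0] if single else out


def make_warp_grid(height: int, width: int, grid_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Source vertex lattice (xs, ys) covering a height x width image."""
    if not 2 <= grid_px <= MAX_GRID_PX:
        raise ValueError(f"grid spacing must be in [2, {MAX_GRID_PX}] px")
    xs = np.arange(0, width - 1 + grid_px, grid_px, dtype=float)
    ys = np.arange(0, height - 1 + grid_px, grid_px, dtype=float)
    xs[-1] = max(xs[-1], width - 1)
    ys[-1] = max(ys[-1], height - 1)
    return xs, ys


def _cross2(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _affine_from_triangles(dst_tri: np.ndarray, src_tri: np.ndarray) -> np.ndarray:
    """2x3 affine A with src = A @ [x_dst, y_dst, 1] for a triangle pair."""
    D = np.column_stack([dst_tri, np.ones(3)])  # (3, 3)
    return np.linalg.solve(D, src_tri).T  # (2, 3)


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h, w = img.shape
    x = np.clip(x, 0.0, w - 1.0)
    y = np.clip(y, 0.0, h - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2)
    fx, fy = x - x0, y - y0
    top = img[y0, x0] * (1 - fx) + img[y0, x0 + 1] * fx
    bot = img[y0 + 1, x0] * (1 - fx) + img[y0 + 1, x0 + 1] * fx
    return top * (1 - fy) + bot * fy


def deform_image(
    img: np.ndarray,
    cp: ControlPointPairs,
    grid_px: int = MAX_GRID_PX,
    *,
    alpha: float = 1.0,
    max_inverted_fraction: float = 0.01,
) -> np.ndarray:
    """Warp a grayscale image so control points move from source to target.

    Grid vertices are mapped with :func:`local_similarity`; each cell is
    split into two triangles (top-left→bottom-right diagonal) and each
    destination triangle is rasterized by inverse-affine bilinear sampling
    of the source.  Destination pixels not covered by any triangle are
    filled with the nearest covered value.  Deterministic.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("image must be 2D grayscale, at least 16x16")
    h, w = img.shape
    xs, ys = make_warp_grid(h, w, grid_px)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    src_vertices = np.column_stack([gx.ravel(), gy.ravel()])
    dst_vertices = local_similarity(src_vertices, cp, alpha=alpha)
    ny, nx = gx.shape
    dst = dst_vertices.reshape(ny, nx, 2)
    src = np.stack([gx, gy], axis=-1)

    out = np.full((h, w), np.nan)
    inverted = 0
    total = 0
    # two triangles per cell: (tl, tr, br) and (tl, br, bl)
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            corners = [(iy, ix), (iy, ix + 1), (iy + 1, ix + 1), (iy + 1, ix)]
            for tri in ((0, 1, 2), (0, 2, 3)):
                d_tri = np.array([dst[corners[t]] for t in tri])
                s_tri = np.array([src[corners[t]] for t in tri])
                total += 1
                area2 = _cross2(d_tri[1] - d_tri[0], d_tri[2] - d_tri[0])
                if area2 < 0:
                    inverted += 1
                    continue
                if area2 == 0:
                    continue
                _fill_triangle(out, img, d_tri, s_tri)
    if inverted > max_inverted_fraction * total:
        raise ValueError(
            f"{inverted}/{total} destination triangles inverted "
            f"(> {max_inverted_fraction:.0%} allowed)"
        )
    nan = np.isnan(out)
    if nan.any():
        from scipy.ndimage import distance_transform_edt

        idx = distance_transform_edt(nan, return_distances=False, return_indices=True)
        out = out[tuple(idx)]
    return out


def _fill_triangle(out: np.ndarray, img: np.ndarray, d_tri: np.ndarray, s_tri: np.ndarray) -> None:
    h, w = out.shape
    x0 = max(int(np.floor(d_tri[:, 0].min())), 0)
    x1 = min(int(np.ceil(d_tri[:, 0].max())), w - 1)
    y0 = max(int(np.floor(d_tri[:, 1].min())), 0)
    y1 = min(int(np.ceil(d_tri[:, 1].max())), h - 1)
    if x1 < x0 or y1 < y0:
        return
    xx, yy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    P = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
    # barycentric inclusion test (counter-clockwise or clockwise tolerant)
    a, b, c = d_tri
    v0, v1 = b - a, c - a
    den = _cross2(v0, v1)
    v2 = P - a
    l1 = (v2[:, 0] * v1[1] - v2[:, 1] * v1[0]) / den
    l2 = (v0[0] * v2[:, 1] - v0[1] * v2[:, 0]) / den
    eps = 1e-9
    inside = (l1 >= -eps) & (l2 >= -eps) & (l1 + l2 <= 1 + eps)
    if not inside.any():
        return
    A = _affine_from_triangles(d_tri, s_tri)
    Pin = P[inside]
    sx = A[0, 0] * Pin[:, 0] + A[0, 1] * Pin[:, 1] + A[0, 2]
    sy = A[1, 0] * Pin[:, 0] + A[1, 1] * Pin[:, 1] + A[1, 2]
    vals = _bilinear(img, sx, sy)
    ix = Pin[:, 0].astype(int)
    iy = Pin[:, 1].astype(int)
    keep = np.isnan(out[iy, ix])
    out[iy[keep], ix[keep]] = vals[keep]


# --- face rendering -------------------------------------------------------

def face_to_pixel_landmarks(
    d: FaceVector,
    schema: DistanceSchema,
    ref_landmarks: LandmarkSet,
) -> LandmarkSet:
    """Target pixel landmarks for a distance vector, anchored on a reference.

    The reference supplies the facial length in pixels (top→chin), the
    midline x and the top y; the face-frame positions implied by ``d`` are
    then placed symmetrically about that midline.
    """
    if ref_landmarks.frame != PIXEL_FRAME:
        raise ValueError("reference landmarks must be in the pixel frame")
    top = np.array(ref_landmarks["top"])
    chin = np.array(ref_landmarks["chin"])
    length_px = chin[1] - top[1]
    if length_px <= 0:
        raise ValueError("reference face height must be positive")
    mid_x = 0.5 * (top[0] + chin[0])
    face = distances_to_landmarks(d, schema)
    pos = {
        k: (mid_x + x * length_px, top[1] + y * length_px)
        for k, (x, y) in face.positions.items()
    }
    return LandmarkSet(pos, frame=PIXEL_FRAME, pixel_scale=float(length_px))


def render_face(
    reference: np.ndarray,
    ref_landmarks: LandmarkSet,
    d: FaceVector,
    schema: DistanceSchema,
    *,
    grid_px: int = MAX_GRID_PX,
    alpha: float = 1.0,
) -> np.ndarray:
    """Deform a reference portrait so its landmark distances become ``d``."""
    target = face_to_pixel_landmarks(d, schema, ref_landmarks)
    h, w = np.asarray(reference).shape
    for k in target.ids():
        x, y = target[k]
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"target landmark {k!r} outside image bounds")
    cp = ControlPointPairs.from_landmarks(ref_landmarks, target)
    return deform_image(reference, cp, grid_px, alpha=alpha)
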