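"""Face-space metrics and population (pseudo-)distances.

Four metrics between facial vectors are provided:

``euclidean``
    per-coordinate RMS distance in physical coordinates,
    ``||u - v||_2 / sqrt(D)`` with D = 11.
``mahalanobis``
    ``sqrt((u-v)^T C^+ (u-v))`` with the covariance pseudo-inverted on
    its top-k eigenspace (default k = 7, the most varying directions).
``angle``
    the angle subtended between the standardized fluctuation vectors
    ``y(u)``, ``y(v)``, optionally truncated to the top-k principal
    components.
``byatt_rhodes``
    the angle computed in the whitened (Mahalanobis) frame; a
    swappable stand-in for the norm-based identity metric of the
    face-perception literature.

Populations are compared by the mean cross-pair distance, a
*pseudo-distance*: a population has nonzero distance to itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .schema import FaceVector, N_DISTANCES

__all__ = [
    "MetricContext",
    "face_distance",
    "intra_population_distance",
    "population_pseudo_distance",
    "convergence_curve",
]

METRICS = ("euclidean", "mahalanobis", "angle", "byatt_rhodes")


@dataclass
class MetricContext:
    """Everything a non-Euclidean metric needs, fitted once on a dataset."""

    metric: str = "euclidean"
    mean: np.ndarray | None = None
    sigma: np.ndarray | None = None
    covariance: np.ndarray | None = None
    k: int | None = None  # PC truncation (e.g. 7)
    euclidean_norm: str = "sqrt_d"  # "sqrt_d": ||.||/sqrt(D); "d": ||.||/D

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.euclidean_norm not in ("sqrt_d", "d"):
            raise ValueError("euclidean_norm must be 'sqrt_d' or 'd'")
        if self.metric != "euclidean":
            if self.mean is None or self.sigma is None:
                raise ValueError(f"{self.metric} metric needs mean and sigma")
            self.mean = np.asarray(self.mean, dtype=float)
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.metric in ("mahalanobis", "byatt_rhodes"):
            if self.covariance is None:
                raise ValueError(f"{self.metric} metric needs a covariance matrix")
        if self.covariance is not None:
            C = np.asarray(self.covariance, dtype=float)
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            if self.k is not None and not 1 <= self.k <= C.shape[0]:
                raise ValueError("k must be in [1, dimension]")
            self.covariance = C

    @classmethod
    def from_dataset(cls, y_records: np.ndarray, metric: str = "euclidean",
                     k: int | None = None) -> "MetricContext":
        """Fit mean/sigma/covariance of raw coordinate records (rows)."""
        f = np.asarray(y_records, dtype=float)
        mean = f.mean(axis=0)
        sigma = f.std(axis=0, ddof=1)
        yy = (f - mean) / sigma
        cov = np.cov(yy, rowvar=False, ddof=1)
        return cls(metric=metric, mean=mean, sigma=sigma, covariance=cov, k=k)

    # cached eigen-decomposition of the covariance
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            lam, E = np.linalg.eigh(self.covariance)
            self._eig = (lam, E)
        return self._eig

    def standardized(self, v: np.ndarray) -> np.ndarray:
        return (v - self.mean) / self.sigma

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "mean": None if self.mean is None else self.mean.tolist(),
            "sigma": None if self.sigma is None else self.sigma.tolist(),
            "covariance": None
            if self.covariance is None
            else self.covariance.tolist(),
            "k": self.k,
            "euclidean_norm": self.euclidean_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricContext":
        return cls(
            metric=d["metric"],
            mean=None if d.get("mean") is None else np.array(d["mean"]),
            sigma=None if d.get("sigma") is None else np.array(d["sigma"]),
            covariance=None
            if d.get("covariance") is None
            else np.array(d["covariance"]),
            k=d.get("k"),
            euclidean_norm=d.get("euclidean_norm", "sqrt_d"),
        )


def _as_vec(u) -> np.ndarray:
    return u.d if isinstance(u, FaceVector) else np.asarray(u, dtype=float)


def face_distance(u, v, ctx: MetricContext | None = None) -> float:
    """Distance between two facial vectors under the context's metric."""
    ctx = ctx or MetricContext()
    a, b = _as_vec(u), _as_vec(v)
    D = a.shape[0]
    if ctx.metric == "euclidean":
        den = np.sqrt(D) if ctx.euclidean_norm == "sqrt_d" else float(D)
        return float(np.linalg.norm(a - b) / den)
    ya, yb = ctx.standardized(a), ctx.standardized(b)
    if ctx.metric == "angle":
        if ctx.k is not None:
            lam, E = ctx.eigensystem()
            keep = E[:, np.argsort(lam)[::-1][: ctx.k]]
            ya, yb = keep.T @ ya, keep.T @ yb
        return _angle(ya, yb)
    # mahalanobis / byatt_rhodes: whiten on the top-k eigenspace
    lam, E = ctx.eigensystem()
    order = np.argsort(lam)[::-1]
    k = ctx.k if ctx.k is not None else int(np.sum(lam > 1e-12 * lam.max()))
    cols = order[:k]
    lam_k, E_k = lam[cols], E[:, cols]
    if np.any(lam_k <= 0):
        raise ValueError("non-positive eigenvalue in the retained eigenspace")
    wa = (E_k.T @ ya) / np.sqrt(lam_k)
    wb = (E_k.T @ yb) / np.sqrt(lam_k)
    if ctx.metric == "mahalanobis":
        return float(np.linalg.norm(wa - wb))
    return _angle(wa, wb)


def _angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm standardized vector in angle metric")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def _members(P) -> list:
    return list(P.members) if hasattr(P, "members") else list(P)


def intra_population_distance(P, ctx: MetricContext | None = None) -> float:
    """Mean pairwise distance over the N(N-1)/2 unordered member pairs."""
    members = _members(P)
    n = len(members)
    if n < 2:
        raise ValueError("intra-population distance needs at least 2 members")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += face_distance(members[i], members[j], ctx)
    return total / (n * (n - 1) / 2)


def population_pseudo_distance(P, Q, ctx: MetricContext | None = None) -> float:
    """Mean distance over all cross pairs; symmetric, nonzero for P = Q."""
    mp, mq = _members(P), _members(Q)
    if not mp or not mq:
        raise ValueError("empty population")
    total = 0.0
    for u in mp:
        for v in mq:
            total += face_distance(u, v, ctx)
    return total / (len(mp) * len(mq))


def convergence_curve(record, ctx: MetricContext | None = None) -> np.ndarray:
    """Intra-population distance per generation (length T+1), in order."""
    return np.array(
        [intra_population_distance(P, ctx) for P in record.populations]
    )
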