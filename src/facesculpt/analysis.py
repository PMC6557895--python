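"""Statistical battery for sculpted face-space datasets.

Covers: the separation of self-consistency vs inter-subject distance
histograms (t statistic and overlap probability p12), the bootstrapped
correlation matrix of standardized facial coordinates (one vector per
subject per realization), its principal-component decomposition, group
comparisons (e.g. by subject gender) per coordinate or per PC, and
cross-condition coordinate offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MetricContext, intra_population_distance, population_pseudo_distance
from .schema import DISTANCE_COLUMNS, N_DISTANCES, StandardizedDataset

__all__ = [
    "SeparationStats",
    "CorrelationResult",
    "PCAResult",
    "GroupTestResult",
    "separation_stats",
    "gaussian_p12",
    "empirical_p12",
    "study_distance_sets",
    "bootstrap_correlation",
    "pca_decompose",
    "project_pcs",
    "group_coordinate_test",
    "cross_experiment_offset",
]


# --- separation of distance histograms -------------------------------------

@dataclass(frozen=True)
class SeparationStats:
    """Separation between inter-subject and self-consistency histograms.

    ``t = (mu_i - mu_sc) / sqrt(sigma_i^2 + sigma_sc^2)``; under a
    Gaussian approximation of both histograms the probability that a
    same-subject pair is closer than a different-subject pair is
    ``p12 = Phi(t)``.
    """

    mu_i: float
    sigma_i: float
    n_i: int
    mu_sc: float
    sigma_sc: float
    n_sc: int
    t: float
    gaussian_p12: float

    @property
    def se_i(self) -> float:
        return self.sigma_i / np.sqrt(self.n_i)

    @property
    def se_sc(self) -> float:
        return self.sigma_sc / np.sqrt(self.n_sc)


def gaussian_p12(t: float) -> float:
    """Overlap probability Phi(t) of two unit-variance-summed Gaussians."""
    return float(stats.norm.cdf(t))


def separation_stats(inter_dists, sc_dists) -> SeparationStats:
    """Summarize the two distance histograms and their separation."""
    di = np.asarray(inter_dists, dtype=float)
    ds = np.asarray(sc_dists, dtype=float)
    if di.size < 2 or ds.size < 2:
        raise ValueError("need at least 2 distances in each set")
    mu_i, mu_sc = di.mean(), ds.mean()
    s_i, s_sc = di.std(ddof=1), ds.std(ddof=1)
    t = (mu_i - mu_sc) / np.hypot(s_i, s_sc)
    return SeparationStats(
        mu_i=float(mu_i),
        sigma_i=float(s_i),
        n_i=int(di.size),
        mu_sc=float(mu_sc),
        sigma_sc=float(s_sc),
        n_sc=int(ds.size),
        t=float(t),
        gaussian_p12=gaussian_p12(float(t)),
    )


def empirical_p12(
    same_pair_dists,
    diff_pair_dists,
    rng: np.random.Generator | None = None,
    n_samples: int = 100_000,
) -> float:
    """P(same-subject distance < different-subject distance), ties = 1/2.

    Exhaustive over all pairs when |same|*|diff| <= 1e6, otherwise a
    seeded Monte-Carlo estimate over ``n_samples`` independent draws.
    """
    same = np.asarray(same_pair_dists, dtype=float)
    diff = np.asarray(diff_pair_dists, dtype=float)
    if same.size == 0 or diff.size == 0:
        raise ValueError("empty distance set")
    if same.size * diff.size <= 1_000_000:
        less = (same[:, None] < diff[None, :]).sum()
        ties = (same[:, None] == diff[None, :]).sum()
        return float((less + 0.5 * ties) / (same.size * diff.size))
    rng = rng or np.random.default_rng()
    x = rng.choice(same, size=n_samples)
    y = rng.choice(diff, size=n_samples)
    return float(np.mean((x < y) + 0.5 * (x == y)))


def study_distance_sets(
    populations: dict[tuple, "object"],
    ctx: MetricContext | None = None,
) -> dict[str, np.ndarray]:
    """Intra, self-consistency and inter-subject distances of a study.

    ``populations`` maps (subject_id, replicate) -> population (any
    sequence of facial vectors).  Self-consistency distances are
    pseudo-distances between replicate pairs of the same subject;
    inter-subject distances are pseudo-distances between the first
    replicates of distinct subjects.
    """
    subjects: dict[object, dict[object, object]] = {}
    for (s, r), pop in populations.items():
        subjects.setdefault(s, {})[r] = pop
    intra = [
        intra_population_distance(pop, ctx)
        for reps in subjects.values()
        for pop in reps.values()
    ]
    sc = []
    for reps in subjects.values():
        keys = sorted(reps)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                sc.append(population_pseudo_distance(reps[keys[i]], reps[keys[j]], ctx))
    firsts = [reps[sorted(reps)[0]] for _, reps in sorted(subjects.items(), key=lambda kv: str(kv[0]))]
    inter = []
    for i in range(len(firsts)):
        for j in range(i + 1, len(firsts)):
            inter.append(population_pseudo_distance(firsts[i], firsts[j], ctx))
    return {
        "intra": np.asarray(intra),
        "self_consistency": np.asarray(sc),
        "inter_subject": np.asarray(inter),
    }


# --- bootstrapped correlation matrix ---------------------------------------

@dataclass
class CorrelationResult:
    """Bootstrap mean/sd/p of the coordinate correlation matrix C_ij."""

    C: np.ndarray
    sd: np.ndarray
    p: np.ndarray
    B: int
    seed: int | None = None
    sign_flip_fraction: np.ndarray | None = None


def _one_per_subject(y: np.ndarray, groups: list[np.ndarray], rng) -> np.ndarray:
    rows = [g[rng.integers(len(g))] for g in groups]
    return y[np.asarray(rows)]


def bootstrap_correlation(
    ds: StandardizedDataset,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    max_redraws: int = 100,
) -> CorrelationResult:
    """One-vector-per-subject bootstrap of the correlation matrix.

    Per realization b one population vector is drawn uniformly for each
    subject — subtracting within-attractor correlations — and the sample
    correlation matrix of the S drawn vectors is computed after
    re-standardizing within the realization.  Element-wise mean, sd over
    realizations, and a two-sided p from the normal approximation
    z = mean/sd are reported, together with the empirical sign-flip
    fraction.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    seed = rng if isinstance(rng, (int, type(None))) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    groups = list(ds.subject_groups().values())
    if len(groups) < 2:
        raise ValueError("need at least 2 subjects")
    f = ds.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
    D = f.shape[1]
    mats = np.empty((B, D, D))
    b = 0
    redraws = 0
    while b < B:
        sample = _one_per_subject(f, groups, rng)
        if np.any(sample.std(axis=0) == 0):
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("too many zero-variance bootstrap realizations")
            continue
        mats[b] = np.corrcoef(sample, rowvar=False)
        b += 1
    mean = mats.mean(axis=0)
    sd = mats.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, np.inf * np.sign(mean))
    p = 2 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(p, 0.0)
    sign_flip = np.mean(np.sign(mats) != np.sign(mean)[None, :, :], axis=0)
    return CorrelationResult(
        C=mean, sd=sd, p=p, B=B, seed=seed, sign_flip_fraction=sign_flip
    )


# --- principal components ---------------------------------------------------

@dataclass
class PCAResult:
    """Eigen-decomposition of C: ascending eigenvalues, orthonormal rows E.

    The projection of a standardized vector y onto the principal axes is
    ``y' = E @ y``; the most varying component is the last one.
    """

    eigenvalues: np.ndarray
    E: np.ndarray  # rows are eigenvectors e^(k)

    def axis(self, k: int) -> np.ndarray:
        return self.E[k]


def pca_decompose(C: np.ndarray) -> PCAResult:
    """Eigen-decompose a symmetric correlation/covariance matrix.

    Eigenvalues ascend; each eigenvector's largest-magnitude entry is made
    positive so the decomposition is deterministic.
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    lam, V = np.linalg.eigh(C)  # ascending
    E = V.T.copy()
    for k in range(E.shape[0]):
        j = np.argmax(np.abs(E[k]))
        if E[k, j] < 0:
            E[k] = -E[k]
    return PCAResult(eigenvalues=lam, E=E)


def project_pcs(y: np.ndarray, pca: PCAResult) -> np.ndarray:
    """Project standardized records (rows) onto the principal axes."""
    return np.atleast_2d(y) @ pca.E.T


# --- group tests ------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Per-coordinate (or per-PC) two-sample location test."""

    labels: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_a: int
    n_b: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [l for l, pv in zip(self.labels, self.p) if pv < alpha]


def _subject_means(ds: StandardizedDataset, mean=None, sigma=None) -> np.ndarray:
    """One standardized vector per subject (mean over its records).

    ``mean``/``sigma`` override the dataset's own standardization
    constants, e.g. with pooled values when comparing two groups.
    """
    if mean is None:
        y = ds.y
    else:
        f = ds.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
        y = (f - mean) / sigma
    return np.stack([y[rows].mean(axis=0) for rows in ds.subject_groups().values()])


def group_coordinate_test(
    ds_a: StandardizedDataset,
    ds_b: StandardizedDataset,
    per: str = "coordinate",
    pca: PCAResult | None = None,
    equal_var: bool = False,
    adjust: str | None = None,
) -> GroupTestResult:
    """Welch (default) or pooled-variance t-test per coordinate or per PC.

    Each subject contributes one vector (the mean of its records in
    standardized coordinates), so subjects — not sculpted vectors — are
    the sampling units.  Standardization uses the pooled mean and sd of
    both datasets, so genuine between-group location shifts survive.
    """
    fa = ds_a.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
    fb = ds_b.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
    pooled = np.vstack([fa, fb])
    p_mean, p_sigma = pooled.mean(axis=0), pooled.std(axis=0, ddof=1)
    if np.any(p_sigma <= 0):
        raise ValueError("degenerate variance in pooled standardization")
    A = _subject_means(ds_a, p_mean, p_sigma)
    Bm = _subject_means(ds_b, p_mean, p_sigma)
    if len(A) < 2 or len(Bm) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if per == "pc":
        if pca is None:
            raise ValueError("per='pc' requires a PCAResult")
        A, Bm = project_pcs(A, pca), project_pcs(Bm, pca)
        labels = [f"pc_{k}" for k in range(A.shape[1])]
    elif per == "coordinate":
        labels = list(DISTANCE_COLUMNS)
    else:
        raise ValueError("per must be 'coordinate' or 'pc'")
    t, p = stats.ttest_ind(A, Bm, axis=0, equal_var=equal_var)
    if adjust == "bh":  # Benjamini-Hochberg FDR
        p = stats.false_discovery_control(p)
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    return GroupTestResult(
        labels=labels,
        mean_a=A.mean(axis=0),
        mean_b=Bm.mean(axis=0),
        t=np.asarray(t),
        p=np.asarray(p),
        n_a=len(A),
        n_b=len(Bm),
    )


def cross_experiment_offset(
    ds_a: StandardizedDataset, ds_b: StandardizedDataset
) -> pd.DataFrame:
    """Mean per-coordinate difference between two conditions, with SE.

    The statistic is the average over all cross pairs (s in A, s' in B)
    of the subject-mean coordinate differences, which equals the
    difference of the two condition means; its standard error scales as
    (S_A * S_B)^(-1/2) when per-subject variances are comparable.
    """
    fa = _subject_frame(ds_a)
    fb = _subject_frame(ds_b)
    diff = fa.mean(axis=0) - fb.mean(axis=0)
    se = np.sqrt(fa.var(axis=0, ddof=1) / len(fa) + fb.var(axis=0, ddof=1) / len(fb))
    return pd.DataFrame(
        {"coordinate": DISTANCE_COLUMNS, "offset": diff, "se": se}
    ).set_index("coordinate")


def _subject_frame(ds: StandardizedDataset) -> np.ndarray:
    f = ds.records[DISTANCE_COLUMNS].to_numpy(dtype=float)
    return np.stack([f[rows].mean(axis=0) for rows in ds.subject_groups().values()])
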