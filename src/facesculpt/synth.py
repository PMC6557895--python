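"""Synthetic data: simulated subject cohorts, full studies, image fixture.

Human choosers and the (non-redistributable) reference photographs are
replaced by programmatic stand-ins with known ground truth, so every
downstream statistic can be scored against what was planted:

* a cohort of simulated subjects whose latent attractors are drawn from
  a multivariate Gaussian in distance space (configurable covariance for
  planted coordinate correlations, plus a group offset emulating e.g. a
  gender split), each choosing via a logistic rule of inverse
  temperature beta;
* a full study — per subject, replicate and experiment tag, one complete
  sculpting run — mirroring the three study conditions: a large
  single-run cohort, a small repeated-run subset for self-consistency,
  and a second-condition tag whose attractors are shifted on designated
  coordinates (emulating a change of reference portrait that leaves the
  "robust" coordinates untouched);
* a deterministic cartoon face image with landmarks at the schema's
  reference positions, replacing a real portrait in warping tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolve import EngineConfig, ExperimentRecord, SimulatedSubject, run_experiment
from .metrics import MetricContext
from .schema import (
    DISTANCE_COLUMNS,
    DistanceSchema,
    FaceVector,
    LandmarkSet,
    N_DISTANCES,
    PIXEL_FRAME,
    default_schema,
    distances_to_landmarks,
    project_to_constraint,
)

__all__ = [
    "SynthCohortConfig",
    "StudyDataset",
    "sample_cohort",
    "run_synthetic_study",
    "make_fixture_image",
    "planted_covariance",
]


def planted_covariance(
    rel_sd: float | np.ndarray = 0.25,
    correlations: dict[tuple[int, int], float] | None = None,
    schema: DistanceSchema | None = None,
) -> np.ndarray:
    """Diagonal attractor covariance with optional planted pair correlations.

    ``rel_sd`` is the attractor standard deviation *relative to each
    coordinate's reference value*, so wide coordinates (face width) vary
    proportionally more than narrow ones (eye width), as anatomy does.
    The default 0.25 spreads attractors over most of the plausible
    (reference ± 50 %) range.
    """
    schema = schema or default_schema()
    sd = np.broadcast_to(np.asarray(rel_sd, dtype=float), (N_DISTANCES,)) * schema.reference
    C = np.diag(sd**2)
    for (i, j), rho in (correlations or {}).items():
        C[i, j] = C[j, i] = rho * sd[i] * sd[j]
    lam = np.linalg.eigvalsh(C)
    if lam.min() < -1e-12:
        raise ValueError("planted covariance is not positive semidefinite")
    return C


@dataclass
class SynthCohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the human study layout: S subjects in two balanced
    gender-like groups, attractors spread around the schema reference
    with sd equal to 25 % of each coordinate's reference value, logistic
    choice noise beta = 6, and m replicates per subject.
    """

    S: int = 20
    groups: tuple[str, ...] = ("A", "B")
    group_fractions: tuple[float, ...] = (0.5, 0.5)
    attractor_mean: np.ndarray | None = None  # defaults to schema reference
    attractor_cov: np.ndarray | None = None  # defaults to planted_covariance()
    group_offset: np.ndarray | None = None  # added to the last group's mean
    attractor_distribution: str = "gaussian"  # or "uniform" (within bounds)
    beta: float = 6.0
    m: int = 1
    tags: tuple[str, ...] = ("E1",)
    tag_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    schema: DistanceSchema = field(default_factory=default_schema)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.groups) != len(self.group_fractions) or abs(
            sum(self.group_fractions) - 1.0
        ) > 1e-9:
            raise ValueError("group fractions must match groups and sum to 1")
        if self.attractor_mean is None:
            self.attractor_mean = self.schema.reference.copy()
        if self.attractor_cov is None:
            self.attractor_cov = planted_covariance(schema=self.schema)


def sample_cohort(
    cfg: SynthCohortConfig, rng: np.random.Generator | int | None = None
) -> list[SimulatedSubject]:
    """Draw S simulated subjects with Gaussian attractors and group offsets.

    Attractors are drawn from N(mean, cov), the group offset is added to
    the last group's draws, and each attractor is projected onto the
    h = 1 constraint and the schema bounds.  Per-subject choice noise
    streams are split off the master rng, so the cohort is reproducible
    from a single seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    counts = np.floor(np.asarray(cfg.group_fractions) * cfg.S).astype(int)
    counts[-1] = cfg.S - counts[:-1].sum()
    labels = [g for g, c in zip(cfg.groups, counts) for _ in range(c)]
    if cfg.attractor_distribution == "uniform":
        draws = rng.uniform(cfg.schema.lo, cfg.schema.hi, size=(cfg.S, N_DISTANCES))
    elif cfg.attractor_distribution == "gaussian":
        draws = rng.multivariate_normal(
            cfg.attractor_mean, cfg.attractor_cov, size=cfg.S, method="svd"
        )
    else:
        raise ValueError("attractor_distribution must be 'gaussian' or 'uniform'")
    if cfg.group_offset is not None:
        off = np.asarray(cfg.group_offset, dtype=float)
        for i, g in enumerate(labels):
            if g == cfg.groups[-1]:
                draws[i] += off
    subjects = []
    for i, (row, g) in enumerate(zip(draws, labels)):
        attractor = project_to_constraint(row, cfg.schema)
        subjects.append(
            SimulatedSubject(
                attractor=attractor,
                beta=cfg.beta,
                metric=None,  # euclidean
                rng=np.random.default_rng(rng.integers(2**31)),
                group=g,
            )
        )
    return subjects


@dataclass
class StudyDataset:
    """A full simulated study plus its ground truth.

    ``records`` is population-CSV-shaped: one row per sculpted vector
    with experiment_id, subject_id, replicate, generation, member and
    d_0..d_10 columns.  Ground-truth attractors and group labels are kept
    for recovery scoring.
    """

    records: pd.DataFrame
    attractors: dict[int, FaceVector]
    groups: dict[int, str]
    tag_shifts: dict[str, np.ndarray]
    config: SynthCohortConfig

    def final_populations(
        self, tag: str | None = None
    ) -> dict[tuple[int, int], list[FaceVector]]:
        """(subject, replicate) -> final-generation members, optionally by tag."""
        df = self.records
        if tag is not None:
            df = df[df["experiment_id"] == tag]
        df = df[df["generation"] == df["generation"].max()]
        out: dict[tuple[int, int], list[FaceVector]] = {}
        for (s, r), grp in df.groupby(["subject_id", "replicate"]):
            vecs = grp.sort_values("member")[DISTANCE_COLUMNS].to_numpy()
            out[(int(s), int(r))] = [FaceVector(v) for v in vecs]
        return out

    def final_records(self, tag: str | None = None) -> pd.DataFrame:
        df = self.records
        if tag is not None:
            df = df[df["experiment_id"] == tag]
        return df[df["generation"] == df["generation"].max()].reset_index(drop=True)


def run_synthetic_study(
    cohort: list[SimulatedSubject],
    engine_cfg: EngineConfig,
    m: int = 1,
    tags: tuple[str, ...] = ("E1",),
    rng: np.random.Generator | int | None = None,
    tag_shifts: dict[str, np.ndarray] | None = None,
    cohort_cfg: SynthCohortConfig | None = None,
    keep_generations: str = "final",
) -> StudyDataset:
    """Run one full sculpting experiment per (subject, replicate, tag).

    A tag with an entry in ``tag_shifts`` shifts that condition's
    attractors by the given coordinate vector (projected back onto the
    constraint), emulating a second reference portrait; coordinates with
    zero shift behave as condition-robust ones.

    ``keep_generations``: "final" stores only generation T (the study
    outcome); "all" stores every generation (for convergence curves).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tag_shifts = tag_shifts or {}
    rows = []
    attractors: dict[int, FaceVector] = {}
    groups: dict[int, str] = {}
    for s, subject in enumerate(cohort):
        attractors[s] = subject.attractor
        groups[s] = subject.group or ""
        for tag in tags:
            chooser = subject
            if tag in tag_shifts:
                shifted = project_to_constraint(
                    subject.attractor.d + np.asarray(tag_shifts[tag]),
                    engine_cfg.schema,
                )
                chooser = SimulatedSubject(
                    attractor=shifted,
                    beta=subject.beta,
                    metric=subject.metric,
                    rng=subject.rng,
                    group=subject.group,
                )
            for rep in range(m):
                rec = run_experiment(
                    engine_cfg, chooser, np.random.default_rng(rng.integers(2**31))
                )
                gens = (
                    [rec.populations[-1]]
                    if keep_generations == "final"
                    else rec.populations
                )
                for pop in gens:
                    for n, member in enumerate(pop.members):
                        rows.append(
                            (tag, s, rep, pop.generation, n, *member.d)
                        )
    records = pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "subject_id",
            "replicate",
            "generation",
            "member",
            *DISTANCE_COLUMNS,
        ],
    )
    return StudyDataset(
        records=records,
        attractors=attractors,
        groups=groups,
        tag_shifts=tag_shifts,
        config=cohort_cfg or SynthCohortConfig(S=len(cohort), m=m, tags=tags),
    )


# --- image fixture ----------------------------------------------------------

def make_fixture_image(
    width: int = 300,
    height: int = 400,
    schema: DistanceSchema | None = None,
    *,
    fiducials: bool = False,
    texture_amplitude: float = 8.0,
) -> tuple[np.ndarray, LandmarkSet]:
    """Deterministic cartoon portrait + pixel landmarks for warping tests.

    A smooth-shaded elliptical head with eyes, nose, mouth and jaw lines
    drawn at the schema's reference landmark positions, overlaid with a
    low-amplitude smooth texture so that warps are numerically
    detectable everywhere.  With ``fiducials=True`` a dark dot is burned
    in at every landmark for round-trip tracking.
    """
    if width < 64 or height < 64:
        raise ValueError("fixture must be at least 64x64")
    schema = schema or default_schema()
    face = distances_to_landmarks(FaceVector(schema.reference), schema)

    # place the unit-length face frame into pixels with margins
    length_px = 0.8 * height
    top_y = 0.1 * height
    mid_x = width / 2.0
    lm = {
        k: (mid_x + x * length_px, top_y + y * length_px)
        for k, (x, y) in face.positions.items()
    }
    landmarks = LandmarkSet(lm, frame=PIXEL_FRAME, pixel_scale=float(length_px))

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    img = np.full((height, width), 210.0)

    # head: shaded ellipse centred mid-face
    cy = top_y + 0.5 * length_px
    ax_ = 0.5 * schema.reference[5] * length_px * 1.15
    ay = 0.55 * length_px
    r2 = ((xx - mid_x) / ax_) ** 2 + ((yy - cy) / ay) ** 2
    head = r2 <= 1.0
    img[head] = 150.0 + 40.0 * (1.0 - r2[head])

    # smooth deterministic texture (detectable under warps)
    img += texture_amplitude * np.sin(2 * np.pi * xx / 23.0) * np.sin(
        2 * np.pi * yy / 29.0
    )

    def disk(cx_, cy_, rad, value):
        m = (xx - cx_) ** 2 + (yy - cy_) ** 2 <= rad**2
        img[m] = value

    eye_r = 0.45 * schema.reference[8] * length_px
    for side in ("l", "r"):
        ex, ey = lm[f"eye_center_{side}"]
        disk(ex, ey, eye_r, 60.0)
        disk(ex, ey, 0.4 * eye_r, 20.0)
    nx, ny = lm["nose_end"]
    wl, wr = lm["nose_wing_l"], lm["nose_wing_r"]
    nose = (np.abs(yy - ny) < 2.5) & (xx >= wl[0]) & (xx <= wr[0])
    img[nose] = 90.0
    mcx, mcy = lm["mouth_center"]
    ml, mr = lm["mouth_corner_l"], lm["mouth_corner_r"]
    mouth = (np.abs(yy - mcy) < 3.5) & (xx >= ml[0]) & (xx <= mr[0])
    img[mouth] = 70.0
    jl, jr = lm["jaw_l"], lm["jaw_r"]
    jaw = (np.abs(yy - jl[1]) < 1.5) & (xx >= jl[0]) & (xx <= jr[0])
    img[jaw] = 120.0

    if fiducials:
        for k in schema.landmark_ids:
            disk(lm[k][0], lm[k][1], 2.0, 0.0)

    return np.clip(img, 0.0, 255.0), landmarks
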