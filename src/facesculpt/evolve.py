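"""Interactive differential-evolution sculpting engine.

A population of N facial vectors evolves under selection exerted by a
*chooser* — a human at a terminal or a simulated subject.  At every
generation each member n is challenged by a DE/rand/1/bin offspring; the
pair is presented in randomized left/right order and the chooser's pick
becomes member n of the next generation.  A full run of T generations
therefore costs exactly N*T binary choices (280 with the default
N = 28, T = 10).

The offspring is generated from the facial vectors alone; rendering a
facial image for presentation is optional and only needed for human
choosers, so large simulation studies skip imaging entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from . import metrics as _metrics
from .schema import (
    DistanceSchema,
    FaceVector,
    N_DISTANCES,
    default_schema,
    project_to_constraint,
)

__all__ = [
    "EngineConfig",
    "Population",
    "Choice",
    "ChoiceLog",
    "Chooser",
    "SimulatedSubject",
    "RandomChooser",
    "ExperimentRecord",
    "init_population",
    "propose_offspring",
    "run_generation",
    "run_experiment",
]


@dataclass
class EngineConfig:
    """Differential-evolution engine parameters.

    N, T, mu and rho default to the standard study conditions
    (N = 28 members, T = 10 generations, differential weight mu = 0.15,
    per-coordinate crossover probability rho = 1).
    """

    N: int = 28
    T: int = 10
    mu: float = 0.15
    rho: float = 1.0
    schema: DistanceSchema = field(default_factory=default_schema)
    seed: int | None = None
    randomize_sides: bool = True

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("DE needs N >= 4 (target + 3 distinct partners)")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class Population:
    generation: int
    members: list[FaceVector]

    def __len__(self) -> int:
        return len(self.members)

    def as_array(self) -> np.ndarray:
        return np.stack([m.d for m in self.members])

    def centroid(self) -> np.ndarray:
        return self.as_array().mean(axis=0)


@dataclass(frozen=True)
class Choice:
    generation: int
    member: int
    parent_side: str  # "left" | "right"
    chosen_side: str
    offspring_won: bool


ChoiceLog = list


class Chooser(Protocol):
    """Behavioral contract: a total binary preference between two faces.

    Implementations must be side-blind — they receive the two options in
    randomized order and return 0 (first) or 1 (second).
    """

    def choose(self, option_a: FaceVector, option_b: FaceVector) -> int: ...


@dataclass
class SimulatedSubject:
    """A chooser with a latent attractor and logistic choice noise.

    The probability of picking option a over option b is logistic in the
    *relative* metric-distance difference to the attractor ``f*``
    (a Weber-fraction discrimination rule, invariant to the overall
    distance scale)::

        P(a) = 1 / (1 + exp(-beta * (d_b - d_a) / (d_a + d_b)))

    with ``d_x = dist(x, f*)``.  ``beta = 0`` is the null model
    (uniformly random choices); ``beta = inf`` is a deterministic
    nearest-to-attractor chooser (ties go to the first option).
    """

    attractor: FaceVector
    beta: float = 6.0
    metric: _metrics.MetricContext | None = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    group: str | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def choose(self, option_a: FaceVector, option_b: FaceVector) -> int:
        da = _metrics.face_distance(option_a, self.attractor, self.metric)
        db = _metrics.face_distance(option_b, self.attractor, self.metric)
        if np.isinf(self.beta):
            return 0 if da <= db else 1
        total = da + db
        if total == 0:
            return 0 if self.rng.random() < 0.5 else 1
        p_a = 1.0 / (1.0 + np.exp(-self.beta * (db - da) / total))
        return 0 if self.rng.random() < p_a else 1


@dataclass
class RandomChooser:
    """The null model: left/right choices are uniformly random."""

    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def choose(self, option_a: FaceVector, option_b: FaceVector) -> int:
        return int(self.rng.integers(2))


@dataclass
class ExperimentRecord:
    """All T+1 populations of one sculpting run plus the full choice log."""

    config: EngineConfig
    populations: list[Population]
    choices: ChoiceLog
    seed: int | None = None
    chooser_info: dict = field(default_factory=dict)

    @property
    def final(self) -> Population:
        return self.populations[-1]


def init_population(config: EngineConfig, rng: np.random.Generator) -> Population:
    """N random vectors, coordinate-wise uniform within bounds, projected."""
    s = config.schema
    raw = rng.uniform(s.lo, s.hi, size=(config.N, N_DISTANCES))
    members = [project_to_constraint(r, s) for r in raw]
    return Population(generation=0, members=members)


def propose_offspring(
    pop: Population, n: int, config: EngineConfig, rng: np.random.Generator
) -> FaceVector:
    """DE/rand/1/bin offspring for member n, projected onto the constraint.

    Mutant ``m = f(a) + mu * (f(b) - f(c))`` from three distinct partners
    a, b, c != n; binomial crossover with the parent at rate rho, with one
    uniformly chosen coordinate always taken from the mutant.
    """
    N = len(pop)
    candidates = np.delete(np.arange(N), n)
    a, b, c = rng.choice(candidates, size=3, replace=False)
    fa, fb, fc = (pop.members[i].d for i in (a, b, c))
    mutant = fa + config.mu * (fb - fc)
    parent = pop.members[n].d
    take = rng.random(N_DISTANCES) < config.rho
    take[rng.integers(N_DISTANCES)] = True  # forced coordinate
    trial = np.where(take, mutant, parent)
    return project_to_constraint(trial, config.schema)


def run_generation(
    pop: Population,
    chooser: Chooser,
    config: EngineConfig,
    rng: np.random.Generator,
    renderer: Callable[[FaceVector], object] | None = None,
) -> tuple[Population, ChoiceLog]:
    """One generation: N duels parent-vs-offspring, winners survive."""
    next_members: list[FaceVector] = []
    log: ChoiceLog = []
    for n in range(len(pop)):
        offspring = propose_offspring(pop, n, config, rng)
        parent = pop.members[n]
        parent_left = bool(rng.integers(2)) if config.randomize_sides else True
        left, right = (parent, offspring) if parent_left else (offspring, parent)
        if renderer is not None:
            pick = chooser.choose(renderer(left), renderer(right))
        else:
            pick = chooser.choose(left, right)
        if pick not in (0, 1):
            raise ValueError("chooser must return 0 or 1")
        winner = left if pick == 0 else right
        chosen_side = "left" if pick == 0 else "right"
        next_members.append(winner)
        log.append(
            Choice(
                generation=pop.generation,
                member=n,
                parent_side="left" if parent_left else "right",
                chosen_side=chosen_side,
                offspring_won=winner is offspring,
            )
        )
    return Population(generation=pop.generation + 1, members=next_members), log


def run_experiment(
    config: EngineConfig,
    chooser: Chooser,
    rng: np.random.Generator | int | None = None,
    renderer: Callable[[FaceVector], object] | None = None,
) -> ExperimentRecord:
    """A full sculpting run: T generations, exactly N*T logged choices."""
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = config.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = config.seed
    pop = init_population(config, rng)
    populations = [pop]
    choices: ChoiceLog = []
    for _ in range(config.T):
        pop, log = run_generation(pop, chooser, config, rng, renderer)
        populations.append(pop)
        choices.extend(log)
    info = {"type": type(chooser).__name__}
    if isinstance(chooser, SimulatedSubject):
        info.update(beta=chooser.beta, group=chooser.group)
    return ExperimentRecord(
        config=config,
        populations=populations,
        choices=choices,
        seed=seed,
        chooser_info=info,
    )
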