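"""Evolutionary engine: populations of unique-integer chromosomes.

A chromosome is a fixed-length vector of *unique* 1-based feature indices —
one candidate feature subset. The engine evolves a population of them with
elitism, tournament or roulette-wheel selection, one- or two-point crossover
(with a uniqueness repair), and index-replacement mutation. The desired
subset-size *range* is handled by running one GA per candidate length and
letting the evaluation layer choose among the winners.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import ClassLabels, FeatureMatrix
from .fitness import FitnessEvaluator

__all__ = [
    "Chromosome",
    "Population",
    "GAConfig",
    "EvolutionTrace",
    "init_population",
    "evaluate_population",
    "select_tournament",
    "select_roulette",
    "crossover_one_point",
    "crossover_two_point",
    "repair_duplicates",
    "mutate",
    "next_generation",
    "run_ga",
    "run_length_sweep",
]


@dataclass(frozen=True)
class Chromosome:
    """An ordered vector of distinct feature indices in 1..m."""

    genes: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        genes = tuple(int(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        if len(genes) < 2:
            raise ValueError(f"chromosome length must be >=2, got {len(genes)}")
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes in chromosome: {genes}")
        if min(genes) < 1:
            raise ValueError(f"gene indices must be >=1: {genes}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Population:
    """k same-length chromosomes at a given generation."""

    chromosomes: tuple[Chromosome, ...]
    generation: int = 0

    def __post_init__(self) -> None:
        chroms = tuple(self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if not chroms:
            raise ValueError("population is empty")
        lengths = {len(c) for c in chroms}
        if len(lengths) != 1:
            raise ValueError(f"mixed chromosome lengths: {sorted(lengths)}")

    @property
    def size(self) -> int:
        return len(self.chromosomes)

    def fitnesses(self) -> np.ndarray:
        vals = [c.fitness for c in self.chromosomes]
        if any(v is None for v in vals):
            raise ValueError("population not fully evaluated")
        return np.array(vals, dtype=float)

    def best(self) -> Chromosome:
        f = self.fitnesses()
        return self.chromosomes[int(np.argmax(f))]


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary hyperparameters.

    Defaults follow common GA practice for this method: population of 100,
    100 generations, per-gene mutation probability 0.1, crossover rate 0.8,
    2 elite chromosomes, binary tournament selection, one-point crossover.
    ``l_min..l_max`` is the range of candidate subset sizes swept by
    :func:`run_length_sweep`.
    """

    l_min: int = 5
    l_max: int = 20
    k: int = 100
    iterations: int = 100
    mutation_prob: float = 0.1
    crossover_rate: float = 0.8
    elite_count: int = 2
    selection: str = "tournament"
    tournament_size: int = 2
    crossover: str = "one_point"
    mutation_mode: str = "per_gene"
    seed: int = 0
    plateau_window: int | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.l_min <= self.l_max:
            raise ValueError(f"need 2 <= l_min <= l_max, got {self.l_min}..{self.l_max}")
        if not 0 <= self.elite_count < self.k:
            raise ValueError("elite_count must be in [0, k)")
        for name in ("mutation_prob", "crossover_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.selection not in ("tournament", "roulette"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.crossover not in ("one_point", "two_point"):
            raise ValueError(f"unknown crossover {self.crossover!r}")
        if self.mutation_mode not in ("per_gene", "per_chromosome"):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >=2")


@dataclass
class EvolutionTrace:
    """Per-generation summary of one GA run."""

    seed: int
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_genes: list[tuple[int, ...]] = field(default_factory=list)
    total_evaluations: int = 0

    def record(self, pop: Population) -> None:
        f = pop.fitnesses()
        self.best_fitness.append(float(f.max()))
        self.mean_fitness.append(float(f.mean()))
        self.best_genes.append(pop.best().genes)


def init_population(m: int, l: int, k: int, rng: np.random.Generator) -> Population:
    """k random chromosomes of l distinct indices uniform in 1..m."""
    if l >= m:
        raise ValueError(f"chromosome length {l} must be < number of features {m}")
    if k < 2:
        raise ValueError("population size must be >=2")
    chroms = tuple(
        Chromosome(tuple(int(g) + 1 for g in rng.choice(m, size=l, replace=False)))
        for _ in range(k)
    )
    return Population(chroms, generation=0)


def evaluate_population(pop: Population, evaluator: FitnessEvaluator) -> Population:
    """Attach fitness to every chromosome (cached subsets are not re-scored)."""
    chroms = tuple(
        c if c.fitness is not None else replace(c, fitness=evaluator(c.genes))
        for c in pop.chromosomes
    )
    return Population(chroms, generation=pop.generation)


def _argmax_random_ties(values: np.ndarray, rng: np.random.Generator) -> int:
    best = values.max()
    ties = np.flatnonzero(values == best)
    return int(ties[0] if ties.size == 1 else rng.choice(ties))


def select_tournament(
    pop: Population, rng: np.random.Generator, tournament_size: int = 2
) -> Chromosome:
    """Best of ``tournament_size`` uniform draws with replacement; ties random."""
    if tournament_size < 2:
        raise ValueError("tournament_size must be >=2")
    f = pop.fitnesses()
    entrants = rng.integers(0, pop.size, size=tournament_size)
    winner = entrants[_argmax_random_ties(f[entrants], rng)]
    return pop.chromosomes[int(winner)]


def select_roulette(pop: Population, rng: np.random.Generator) -> Chromosome:
    """Fitness-proportional draw; uniform when total fitness is zero."""
    f = pop.fitnesses()
    total = f.sum()
    p = None if total <= 0 else f / total
    return pop.chromosomes[int(rng.choice(pop.size, p=p))]


def repair_duplicates(ch: Chromosome | tuple, m: int, rng: np.random.Generator) -> Chromosome:
    """Replace repeated genes (after their first occurrence) with uniform
    draws from the indices currently absent from the chromosome."""
    genes = list(getattr(ch, "genes", ch))
    if len(genes) > m:
        raise ValueError(f"cannot make {len(genes)} genes unique within 1..{m}")
    present = set()
    dup_slots = []
    for i, g in enumerate(genes):
        if g in present:
            dup_slots.append(i)
        else:
            present.add(g)
    if not dup_slots:
        return ch if isinstance(ch, Chromosome) else Chromosome(tuple(genes))
    absent = [g for g in range(1, m + 1) if g not in present]
    picks = rng.choice(len(absent), size=len(dup_slots), replace=False)
    for i, slot in enumerate(dup_slots):
        genes[slot] = absent[int(picks[i])]
    return Chromosome(tuple(genes))


def _raw_one_point(a: list, b: list, rng: np.random.Generator):
    l = len(a)
    cut = int(rng.integers(1, l))  # cut in 1..l-1
    return a[:cut] + b[cut:], b[:cut] + a[cut:]


def crossover_one_point(
    parent_a: Chromosome, parent_b: Chromosome, rng: np.random.Generator, m: int
) -> tuple[Chromosome, Chromosome]:
    """Swap tails at a uniform cut in 1..l-1, then repair duplicates."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length")
    ca, cb = _raw_one_point(list(parent_a.genes), list(parent_b.genes), rng)
    return repair_duplicates(tuple(ca), m, rng), repair_duplicates(tuple(cb), m, rng)


def crossover_two_point(
    parent_a: Chromosome, parent_b: Chromosome, rng: np.random.Generator, m: int
) -> tuple[Chromosome, Chromosome]:
    """Swap the middle segment between two distinct cuts, then repair."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length")
    l = len(parent_a)
    if l < 3:
        raise ValueError("two-point crossover needs length >=3")
    c1, c2 = sorted(rng.choice(np.arange(1, l), size=2, replace=False).tolist())
    a, b = list(parent_a.genes), list(parent_b.genes)
    ca = a[:c1] + b[c1:c2] + a[c2:]
    cb = b[:c1] + a[c1:c2] + b[c2:]
    return repair_duplicates(tuple(ca), m, rng), repair_duplicates(tuple(cb), m, rng)


def mutate(
    ch: Chromosome,
    mutation_prob: float,
    m: int,
    rng: np.random.Generator,
    mode: str = "per_gene",
) -> Chromosome:
    """Index-replacement mutation preserving uniqueness.

    ``per_gene``: each position independently, with probability
    ``mutation_prob``, is replaced by a uniform draw from the indices not
    currently in the chromosome. ``per_chromosome``: with probability
    ``mutation_prob`` exactly one uniformly chosen position is replaced.
    """
    genes = list(ch.genes)
    if mode == "per_gene":
        hits = np.flatnonzero(rng.random(len(genes)) < mutation_prob)
    elif mode == "per_chromosome":
        hits = (
            np.array([rng.integers(0, len(genes))])
            if rng.random() < mutation_prob
            else np.array([], dtype=int)
        )
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    if hits.size == 0:
        return ch
    present = set(genes)
    for i in hits:
        absent = [g for g in range(1, m + 1) if g not in present]
        if not absent:
            break
        new = absent[int(rng.integers(0, len(absent)))]
        present.discard(genes[int(i)])
        present.add(new)
        genes[int(i)] = new
    return Chromosome(tuple(genes))


def _elite_indices(f: np.ndarray, elite_count: int) -> np.ndarray:
    # stable sort on -fitness: ties resolved by first index order
    order = np.argsort(-f, kind="stable")
    return order[:elite_count]


def next_generation(
    pop: Population,
    config: GAConfig,
    m: int,
    rng: np.random.Generator,
    evaluator: FitnessEvaluator,
) -> Population:
    """One evolutionary step: elitism, selection, crossover, mutation.

    The ``elite_count`` fittest chromosomes pass unchanged; remaining slots
    are filled by pairs of selected parents that recombine with probability
    ``crossover_rate`` (and are cloned otherwise), each child then mutated.
    """
    f = pop.fitnesses()
    elites = [pop.chromosomes[i] for i in _elite_indices(f, config.elite_count)]

    def pick() -> Chromosome:
        if config.selection == "tournament":
            return select_tournament(pop, rng, config.tournament_size)
        return select_roulette(pop, rng)

    children: list[Chromosome] = []
    need = pop.size - len(elites)
    while len(children) < need:
        pa, pb = pick(), pick()
        if rng.random() < config.crossover_rate:
            if config.crossover == "one_point":
                ca, cb = crossover_one_point(pa, pb, rng, m)
            else:
                ca, cb = crossover_two_point(pa, pb, rng, m)
        else:
            ca, cb = pa, pb
        for child in (ca, cb):
            if len(children) >= need:
                break
            children.append(
                mutate(child, config.mutation_prob, m, rng, config.mutation_mode)
            )

    new = Population(tuple(elites) + tuple(children), generation=pop.generation + 1)
    return evaluate_population(new, evaluator)


def run_ga(
    matrix: FeatureMatrix,
    labels: ClassLabels,
    l: int,
    config: GAConfig,
    seed: int | None = None,
) -> tuple[Chromosome, EvolutionTrace]:
    """Evolve one fixed-length population; return best-ever chromosome + trace.

    Fully reproducible from the seed (``config.seed`` unless overridden).
    With ``plateau_window`` set, stops early once the best fitness has not
    improved over that many consecutive generations.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    evaluator = FitnessEvaluator(matrix, labels)
    trace = EvolutionTrace(seed=seed)

    pop = evaluate_population(
        init_population(matrix.n_features, l, config.k, rng), evaluator
    )
    trace.record(pop)
    stall = 0
    for _ in range(config.iterations):
        pop = next_generation(pop, config, matrix.n_features, rng, evaluator)
        improved = trace.best_fitness and pop.fitnesses().max() > trace.best_fitness[-1]
        trace.record(pop)
        stall = 0 if improved else stall + 1
        if config.plateau_window is not None and stall >= config.plateau_window:
            break
    trace.total_evaluations = evaluator.n_evaluations
    return pop.best(), trace


def run_length_sweep(
    matrix: FeatureMatrix,
    labels: ClassLabels,
    config: GAConfig,
) -> dict[int, tuple[Chromosome, EvolutionTrace]]:
    """Independent GA run per candidate length in ``l_min..l_max``.

    Per-length seeds are ``config.seed + l`` — distinct across lengths and
    deterministic given the configured seed.
    """
    if config.l_max >= matrix.n_features:
        raise ValueError(
            f"l_max {config.l_max} must be < number of features {matrix.n_features}"
        )
    out: dict[int, tuple[Chromosome, EvolutionTrace]] = {}
    for l in range(config.l_min, config.l_max + 1):
        out[l] = run_ga(matrix, labels, l, config, seed=config.seed + l)
    return out
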