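"""GA-BP-ANN hybrid: a genetic algorithm over network genomes with
back-propagation as Lamarckian local search.

Each individual encodes a full three-layer network (architecture H plus
its 4H + 1 weights and thresholds).  Fitness is the training RMSE of the
decoded network, so lower is fitter.  Every generation the algorithm
evaluates the population, carries elites over unchanged, selects parents
by tournament, recombines and mutates them, and refines the current top-k
individuals with a short burst of back-propagation, keeping the refined
weights when they improve (Lamarckian, hence monotone in fitness).

The hybrid therefore behaves like a population of restarted BP runs whose
initializations are themselves under selection: the GA supplies global
exploration (including over the hidden-layer size), BP supplies fast
local convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .response_models import NetworkModel, TrainConfig, forward, train_bp

__all__ = [
    "Genome",
    "GAConfig",
    "GARun",
    "genome_from_network",
    "init_population",
    "fitness",
    "select",
    "crossover",
    "mutate",
    "bp_refine",
    "evolve",
]


@dataclass(frozen=True)
class Genome:
    """A network as a GA individual: architecture + flat parameter vector.

    Parameter layout matches :class:`NetworkModel`: 2H input weights
    (row-major), H input thresholds, H output weights, 1 output
    threshold — 4H + 1 genes in total.
    """

    n_hidden: int
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if len(self.params) != 4 * self.n_hidden + 1:
            raise ValueError(
                f"H={self.n_hidden} genome needs {4 * self.n_hidden + 1} "
                f"parameters, got {len(self.params)}"
            )

    def to_network(self) -> NetworkModel:
        h = self.n_hidden
        p = np.asarray(self.params)
        return NetworkModel(
            input_weights=tuple(map(tuple, p[: 2 * h].reshape(h, 2))),
            input_thresholds=tuple(p[2 * h : 3 * h]),
            output_weights=tuple(p[3 * h : 4 * h]),
            output_threshold=float(p[4 * h]),
        )


def genome_from_network(net: NetworkModel) -> Genome:
    params = np.concatenate(
        [
            np.ravel(net.input_weights),
            net.input_thresholds,
            net.output_weights,
            [net.output_threshold],
        ]
    )
    return Genome(n_hidden=net.n_hidden, params=tuple(params))


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the hybrid search (all are artifact choices)."""

    population_size: int = 50
    n_generations: int = 200
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05  # per-gene perturbation probability
    mutation_scale: float = 0.1  # SD of the Gaussian perturbation
    structural_rate: float = 0.05  # probability of H changing by ±1
    elite_count: int = 2
    h_bounds: tuple[int, int] = (3, 12)
    refine_top_k: int = 5
    refine_epochs: int = 150
    refine_lr: float = 0.5
    patience: int = 30  # early stop after this many stagnant generations
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "structural_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population_size < self.elite_count + 2:
            raise ValueError("population_size must be >= elite_count + 2")
        if self.h_bounds[0] < 1 or self.h_bounds[0] > self.h_bounds[1]:
            raise ValueError("invalid h_bounds")


@dataclass
class GARun:
    """Outcome of one evolutionary run."""

    best_genome: Genome
    best_fitness: float  # training RMSE of best_genome
    test_rmse: float | None
    history_best: list[float] = field(default_factory=list)
    history_mean: list[float] = field(default_factory=list)
    config: GAConfig = field(default_factory=GAConfig)
    seed: int = 0


def _random_genome(h: int, rng: np.random.Generator) -> Genome:
    return Genome(n_hidden=h, params=tuple(rng.uniform(-1.0, 1.0, size=4 * h + 1)))


def init_population(config: GAConfig, rng: np.random.Generator | None = None) -> list[Genome]:
    """population_size genomes; H uniform over bounds, genes ~ U(−1, 1)."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.h_bounds
    return [
        _random_genome(int(rng.integers(lo, hi + 1)), rng)
        for _ in range(config.population_size)
    ]


def fitness(genome: Genome, pairs) -> float:
    """Training RMSE of the decoded network on (t1, t2, fraction) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("pairs must be nonempty")
    pred = forward(genome.to_network(), arr[:, 0], arr[:, 1])
    return float(np.sqrt(np.mean((pred - arr[:, 2]) ** 2)))


def select(
    population: list[Genome],
    fitnesses: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> list[Genome]:
    """Tournament selection (minimizing RMSE) of the parent pool.

    Pool size is population_size − elite_count; ties inside a tournament
    resolve to the lower index for determinism.
    """
    fitnesses = np.asarray(fitnesses)
    n = len(population)
    k = min(config.tournament_size, n)
    pool = []
    for _ in range(config.population_size - config.elite_count):
        contenders = rng.choice(n, size=k, replace=False)
        winner = contenders[np.argmin(fitnesses[contenders])]
        pool.append(population[int(winner)])
    return pool


def _unit_blocks(genome: Genome) -> tuple[np.ndarray, np.ndarray]:
    """(H × 4 per-unit blocks [w1, w2, threshold, w_out], output threshold)."""
    h = genome.n_hidden
    p = np.asarray(genome.params)
    blocks = np.column_stack(
        [p[: 2 * h].reshape(h, 2), p[2 * h : 3 * h], p[3 * h : 4 * h]]
    )
    return blocks, p[4 * h]


def _from_blocks(blocks: np.ndarray, out_thr: float) -> Genome:
    h = blocks.shape[0]
    params = np.concatenate(
        [blocks[:, :2].ravel(), blocks[:, 2], blocks[:, 3], [out_thr]]
    )
    return Genome(n_hidden=h, params=tuple(params))


def crossover(
    parent_a: Genome, parent_b: Genome, rng: np.random.Generator
) -> tuple[Genome, Genome]:
    """Recombine two genomes.

    Equal architectures blend arithmetically per gene with a shared
    α ~ U(0, 1).  Unequal architectures keep each parent's H and swap
    hidden-unit blocks after a random one-point cut within the shared
    prefix of min(H_a, H_b) units.
    """
    if parent_a.n_hidden == parent_b.n_hidden:
        alpha = rng.uniform()
        pa = np.asarray(parent_a.params)
        pb = np.asarray(parent_b.params)
        child_a = alpha * pa + (1.0 - alpha) * pb
        child_b = alpha * pb + (1.0 - alpha) * pa
        return (
            Genome(parent_a.n_hidden, tuple(child_a)),
            Genome(parent_b.n_hidden, tuple(child_b)),
        )
    blocks_a, thr_a = _unit_blocks(parent_a)
    blocks_b, thr_b = _unit_blocks(parent_b)
    h_min = min(parent_a.n_hidden, parent_b.n_hidden)
    cut = int(rng.integers(0, h_min + 1))
    new_a, new_b = blocks_a.copy(), blocks_b.copy()
    new_a[:cut], new_b[:cut] = blocks_b[:cut], blocks_a[:cut]
    return _from_blocks(new_a, thr_a), _from_blocks(new_b, thr_b)


def mutate(genome: Genome, config: GAConfig, rng: np.random.Generator) -> Genome:
    """Gaussian per-gene perturbation plus rare ±1 structural change of H."""
    params = np.asarray(genome.params, dtype=float).copy()
    mask = rng.uniform(size=params.shape) < config.mutation_rate
    params[mask] += rng.normal(0.0, config.mutation_scale, size=int(mask.sum()))
    out = Genome(genome.n_hidden, tuple(params))
    if rng.uniform() < config.structural_rate:
        lo, hi = config.h_bounds
        grow = bool(rng.integers(0, 2))
        blocks, thr = _unit_blocks(out)
        if grow and out.n_hidden < hi:
            new_unit = rng.normal(0.0, 0.1, size=(1, 4))
            out = _from_blocks(np.vstack([blocks, new_unit]), thr)
        elif not grow and out.n_hidden > lo:
            drop = int(rng.integers(0, out.n_hidden))
            out = _from_blocks(np.delete(blocks, drop, axis=0), thr)
    return out


def bp_refine(genome: Genome, pairs, config: GAConfig) -> Genome:
    """Lamarckian local search: BP for refine_epochs, kept only if better."""
    if config.refine_epochs < 1:
        return genome
    refined_net = train_bp(
        genome.to_network(),
        pairs,
        TrainConfig(learning_rate=config.refine_lr, epochs=config.refine_epochs),
    )
    refined = genome_from_network(refined_net)
    return refined if fitness(refined, pairs) < fitness(genome, pairs) else genome


def evolve(train_pairs, test_pairs=None, config: GAConfig | None = None) -> GARun:
    """Run the full hybrid loop and return the best-ever genome.

    Per generation: evaluate → BP-refine the top-k → elite carry-over →
    tournament selection → crossover → mutation.  Fitness is training
    RMSE only; test RMSE is reported for the final best genome but never
    optimized.  Early stop after ``patience`` generations without
    improvement of the best fitness.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    population = init_population(config, rng)
    fitnesses = np.array([fitness(g, train_pairs) for g in population])

    best_genome = population[int(np.argmin(fitnesses))]
    best_fit = float(fitnesses.min())
    history_best: list[float] = []
    history_mean: list[float] = []
    stagnant = 0

    for _ in range(config.n_generations):
        # Lamarckian refinement of the current top-k
        order = np.argsort(fitnesses, kind="stable")
        for idx in order[: config.refine_top_k]:
            refined = bp_refine(population[int(idx)], train_pairs, config)
            if refined is not population[int(idx)]:
                population[int(idx)] = refined
                fitnesses[int(idx)] = fitness(refined, train_pairs)

        gen_best = float(fitnesses.min())
        if gen_best < best_fit - 1e-12:
            best_fit = gen_best
            best_genome = population[int(np.argmin(fitnesses))]
            stagnant = 0
        else:
            stagnant += 1
        history_best.append(best_fit)
        history_mean.append(float(fitnesses.mean()))
        if stagnant >= config.patience:
            break

        # elitism: the elite_count best (stable ties) survive unchanged
        order = np.argsort(fitnesses, kind="stable")
        elites = [population[int(i)] for i in order[: config.elite_count]]
        pool = select(population, fitnesses, config, rng)
        children: list[Genome] = []
        for i in range(0, len(pool) - 1, 2):
            a, b = pool[i], pool[i + 1]
            if rng.uniform() < config.crossover_rate:
                a, b = crossover(a, b, rng)
            children.extend((a, b))
        if len(children) < len(pool):  # odd pool size
            children.append(pool[-1])
        children = [mutate(c, config, rng) for c in children]
        population = elites + children
        fitnesses = np.array([fitness(g, train_pairs) for g in population])

    test_rmse = None
    if test_pairs is not None and len(test_pairs) > 0:
        test_rmse = fitness(best_genome, test_pairs)
    return GARun(
        best_genome=best_genome,
        best_fitness=best_fit,
        test_rmse=test_rmse,
        history_best=history_best,
        history_mean=history_mean,
        config=config,
        seed=config.seed,
    )
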