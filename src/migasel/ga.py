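"""Genetic algorithm over binary feature masks.

Each chromosome is a 0/1 vector over the feature columns; its fitness is
the testing accuracy of a network trained on the selected columns (either
a single holdout split or the mean over a K-fold rotation).  Generations
apply fitness-proportional (roulette-wheel) parent selection, single-point
crossover, per-gene mutation, and elitism: the fittest chromosome is
copied unchanged into the next population and is exempt from mutation, so
the best fitness never decreases.

The data split and network seed are frozen once per run, which makes a
chromosome's fitness a pure function of its genes; fitness values are
cached by chromosome content so duplicated chromosomes cost one training.
An optional feature cap assigns fitness 0 to any chromosome selecting
more features than allowed, steering the search toward small subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ann import AnnConfig, SplitSpec, holdout_indices, kfold_evaluate, train_ann


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 50
    iterations: int = 20
    mutation_prob: float = 0.05
    init_one_prob: float = 0.5
    elitism: bool = True
    feature_cap: int | None = None
    fitness_mode: str = "holdout"  # or "kfold_mean"
    K: int = 5
    fitness_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if not 0 <= self.init_one_prob <= 1:
            raise ValueError("init_one_prob must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.fitness_mode not in ("holdout", "kfold_mean"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.fitness_restarts < 1:
            raise ValueError("fitness_restarts must be >= 1")


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_fitness: float
    history: list[tuple[float, float]]  # per-generation (mean, max)
    evaluations: int  # classifier trainings actually run (cache misses)
    config: GaConfig

    @property
    def mean_history(self) -> np.ndarray:
        return np.array([h[0] for h in self.history])

    @property
    def max_history(self) -> np.ndarray:
        return np.array([h[1] for h in self.history])


def init_population(N: int, L: int, p1: float,
                    rng: np.random.Generator) -> np.ndarray:
    """N chromosomes of L independent Bernoulli(p1) genes, as a (N, L) 0/1 array."""
    if N < 1 or L < 1:
        raise ValueError("need N >= 1 and L >= 1")
    if not 0 <= p1 <= 1:
        raise ValueError("p1 must lie in [0, 1]")
    return (rng.random((N, L)) < p1).astype(np.uint8)


def selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    """Roulette-wheel probabilities f_i / sum(f); uniform when all fitness is 0."""
    f = np.asarray(fitness, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitness values must be nonnegative")
    total = f.sum()
    if total == 0:
        return np.full(f.size, 1.0 / f.size)
    return f / total


def single_point_crossover(parent_a: np.ndarray, parent_b: np.ndarray,
                           cpoint: int) -> np.ndarray:
    """Child takes genes 1..cpoint from parent_a, the rest from parent_b."""
    a = np.asarray(parent_a)
    b = np.asarray(parent_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("parents must be 1-D and the same length")
    L = a.size
    if not 1 <= cpoint <= L - 1:
        raise ValueError(f"crossover point must lie in 1..{L - 1}, got {cpoint}")
    return np.concatenate([a[:cpoint], b[cpoint:]]).astype(np.uint8)


def mutate(chrom: np.ndarray, Pm: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each gene independently with probability Pm."""
    if not 0 <= Pm <= 1:
        raise ValueError("Pm must lie in [0, 1]")
    c = np.asarray(chrom).astype(np.uint8)
    flips = rng.random(c.size) < Pm
    return np.where(flips, 1 - c, c).astype(np.uint8)


class FitnessEvaluator:
    """Caching fitness function: classification accuracy of a masked network.

    The holdout indices (or K-fold seed) and the network seed are fixed at
    construction, so fitness is deterministic and cacheable per chromosome.
    """

    def __init__(self, features: np.ndarray, labels, ga_cfg: GaConfig,
                 ann_cfg: AnnConfig, split: SplitSpec):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        self.ga_cfg = ga_cfg
        self.ann_cfg = ann_cfg
        self.split = split
        self._indices = (holdout_indices(labels, split)
                         if ga_cfg.fitness_mode == "holdout" else None)
        self._cache: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, chrom: np.ndarray) -> float:
        chrom = np.asarray(chrom).astype(np.uint8)
        if chrom.size != self.features.shape[1]:
            raise ValueError(
                f"chromosome of {chrom.size} genes for "
                f"{self.features.shape[1]} feature columns")
        key = chrom.tobytes()
        if key in self._cache:
            return self._cache[key]
        ones = int(chrom.sum())
        cap = self.ga_cfg.feature_cap
        if ones == 0 or (cap is not None and ones > cap):
            fit = 0.0
        else:
            # averaging over a few fixed network restarts suppresses the
            # retraining jitter that lets uninformative columns masquerade
            # as fitness gains during the search
            accs = []
            for r in range(self.ga_cfg.fitness_restarts):
                ann_cfg = replace(self.ann_cfg, seed=self.ann_cfg.seed + r)
                if self.ga_cfg.fitness_mode == "holdout":
                    trained = train_ann(self.features, self.labels, ann_cfg,
                                        self.split, mask=chrom,
                                        indices=self._indices)
                    accs.append(trained.metrics()["testing"].accuracy)
                else:
                    res = kfold_evaluate(self.features, self.labels, ann_cfg,
                                         K=self.ga_cfg.K, seed=self.split.seed,
                                         mask=chrom)
                    accs.append(res.averages["testing"].accuracy)
            fit = float(np.mean(accs))
            self.evaluations += 1
        self._cache[key] = fit
        return fit


def evaluate_fitness(chrom: np.ndarray, features: np.ndarray, labels,
                     ga_cfg: GaConfig, ann_cfg: AnnConfig,
                     split: SplitSpec) -> float:
    """One-shot fitness of a single chromosome (no cache reuse across calls)."""
    return FitnessEvaluator(features, labels, ga_cfg, ann_cfg, split)(chrom)


def run_ga(features: np.ndarray, labels, ga_cfg: GaConfig,
           ann_cfg: AnnConfig, split: SplitSpec,
           log=None) -> GAResult:
    """Evolve feature masks for ``ga_cfg.iterations`` generations.

    Each generation evaluates the population, records (mean, max) fitness,
    then builds the next population from one elite copy plus N-1 children
    (roulette parents, single-point crossover, mutation).  The whole run
    is a pure function of (features, labels, configs, seed).
    """
    rng = np.random.default_rng(ga_cfg.seed)
    L = np.asarray(features).shape[1]
    evaluator = FitnessEvaluator(features, labels, ga_cfg, ann_cfg, split)
    pop = init_population(ga_cfg.population_size, L, ga_cfg.init_one_prob, rng)
    history: list[tuple[float, float]] = []
    best_chrom: np.ndarray | None = None
    best_fit = -1.0
    for gen in range(ga_cfg.iterations):
        fitness = np.array([evaluator(c) for c in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_chrom = pop[gen_best].copy()
        if ga_cfg.elitism:
            # the elite survives untouched, so the max column never drops
            history.append((float(fitness.mean()), best_fit))
        else:
            history.append((float(fitness.mean()), float(fitness[gen_best])))
        if log is not None:
            log(gen, history[-1][0], history[-1][1], int(best_chrom.sum()))
        if gen == ga_cfg.iterations - 1:
            break
        probs = selection_probabilities(fitness)
        n_children = ga_cfg.population_size - (1 if ga_cfg.elitism else 0)
        children = np.empty((n_children, L), dtype=np.uint8)
        for j in range(n_children):
            pa, pb = rng.choice(ga_cfg.population_size, size=2, p=probs)
            cpoint = int(rng.integers(1, L))
            child = single_point_crossover(pop[pa], pop[pb], cpoint)
            children[j] = mutate(child, ga_cfg.mutation_prob, rng)
        if ga_cfg.elitism:
            elite = (best_chrom if ga_cfg.elitism else pop[gen_best]).copy()
            pop = np.vstack([elite[None, :], children])
        else:
            pop = children
    assert best_chrom is not None
    return GAResult(best_chrom, best_fit, history, evaluator.evaluations, ga_cfg)
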