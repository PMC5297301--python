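import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migasel.ann import AnnConfig, SplitSpec
from migasel.ga import (
    FitnessEvaluator,
    GaConfig,
    init_population,
    mutate,
    run_ga,
    selection_probabilities,
    single_point_crossover,
)
from migasel.simulate import generate_planted_features


# ------------------------------------------------------------- init
def test_init_all_zero_when_p1_zero(rng):
    pop = init_population(10, 100, 0.0, rng)
    assert pop.shape == (10, 100)
    assert pop.sum() == 0


def test_init_density_half(rng):
    pop = init_population(50, 12336, 0.5, rng)
    mean_ones = pop.sum(axis=1).mean()
    assert abs(mean_ones - 6168) <= 3 * np.sqrt(12336 * 0.25)


def test_sparse_init_density(rng):
    """p1 = 0.25% on 12,336 genes selects ~31 features per chromosome."""
    pop = init_population(50, 12336, 0.0025, rng)
    expected = 12336 * 0.0025  # 30.84
    sd = np.sqrt(12336 * 0.0025 * 0.9975 / 50)
    assert abs(pop.sum(axis=1).mean() - expected) <= 3 * sd


def test_init_reproducible():
    a = init_population(5, 64, 0.3, np.random.default_rng(9))
    b = init_population(5, 64, 0.3, np.random.default_rng(9))
    np.testing.assert_array_equal(a, b)


# ------------------------------------------------------------- selection
def test_uniform_fitness_gives_uniform_probs():
    np.testing.assert_allclose(selection_probabilities(np.ones(8)),
                               np.full(8, 0.125))


def test_proportional_probabilities():
    np.testing.assert_allclose(selection_probabilities([1.0, 3.0]),
                               [0.25, 0.75])


def test_all_zero_fitness_fallback():
    np.testing.assert_allclose(selection_probabilities(np.zeros(4)),
                               [0.25, 0.25, 0.25, 0.25])


def test_negative_fitness_rejected():
    with pytest.raises(ValueError):
        selection_probabilities([-0.1, 1.0])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=50))
def test_probabilities_sum_to_one(fitness):
    probs = selection_probabilities(np.asarray(fitness))
    assert abs(probs.sum() - 1.0) < 1e-12


# ------------------------------------------------------------- crossover
def test_crossover_definition():
    a = np.ones(6, dtype=np.uint8)
    b = np.zeros(6, dtype=np.uint8)
    np.testing.assert_array_equal(single_point_crossover(a, b, 3),
                                  [1, 1, 1, 0, 0, 0])


def test_crossover_identical_parents(rng):
    p = (rng.random(20) < 0.5).astype(np.uint8)
    for c in (1, 10, 19):
        np.testing.assert_array_equal(single_point_crossover(p, p, c), p)


def test_crossover_popcount_identity(rng):
    """popcount(child) = popcount(a[:c]) + popcount(b[c:]) on random cases."""
    for _ in range(100):
        L = int(rng.integers(2, 200))
        a = (rng.random(L) < rng.random()).astype(np.uint8)
        b = (rng.random(L) < rng.random()).astype(np.uint8)
        c = int(rng.integers(1, L))
        child = single_point_crossover(a, b, c)
        assert child.sum() == a[:c].sum() + b[c:].sum()


@pytest.mark.parametrize("c", [0, 6, 99])
def test_crossover_point_out_of_range(c):
    a = np.ones(6, dtype=np.uint8)
    with pytest.raises(ValueError):
        single_point_crossover(a, a, c)


# ------------------------------------------------------------- mutation
def test_mutation_identity_and_complement(rng):
    chrom = (rng.random(50) < 0.5).astype(np.uint8)
    np.testing.assert_array_equal(mutate(chrom, 0.0, rng), chrom)
    np.testing.assert_array_equal(mutate(chrom, 1.0, rng), 1 - chrom)


def test_mutation_flip_count_binomial():
    chrom = np.zeros(12336, dtype=np.uint8)
    flips = [mutate(chrom, 0.05, np.random.default_rng(s)).sum()
             for s in range(20)]
    expected = 12336 * 0.05
    sd = np.sqrt(12336 * 0.05 * 0.95 / 20)
    assert abs(np.mean(flips) - expected) <= 3 * sd


# ------------------------------------------------------------- fitness
def _planted(seed=0):
    return generate_planted_features(n_samples=140, n_features=20,
                                     n_informative=4, effect=1.5, seed=seed)


def test_all_zero_chromosome_fitness_zero():
    X, y, _ = _planted()
    ev = FitnessEvaluator(X, y, GaConfig(), AnnConfig(), SplitSpec())
    assert ev(np.zeros(20, dtype=np.uint8)) == 0.0


def test_feature_cap_zeroes_fitness():
    X, y, _ = _planted()
    ev = FitnessEvaluator(X, y, GaConfig(feature_cap=3), AnnConfig(),
                          SplitSpec())
    chrom = np.zeros(20, dtype=np.uint8)
    chrom[:4] = 1
    assert ev(chrom) == 0.0
    chrom2 = np.zeros(20, dtype=np.uint8)
    chrom2[:3] = 1
    assert ev(chrom2) > 0.0


def test_informative_mask_scores_high():
    """Selecting exactly the class-bearing columns yields >= 0.9 accuracy."""
    fits = []
    for seed in range(5):
        X, y, informative = _planted(seed)
        mask = np.zeros(20, dtype=np.uint8)
        mask[informative] = 1
        ev = FitnessEvaluator(X, y, GaConfig(seed=seed), AnnConfig(seed=seed),
                              SplitSpec(seed=seed))
        fits.append(ev(mask))
    assert np.mean(fits) >= 0.9


def test_fitness_cache_counts_unique_trainings():
    X, y, informative = _planted()
    ev = FitnessEvaluator(X, y, GaConfig(), AnnConfig(), SplitSpec())
    mask = np.zeros(20, dtype=np.uint8)
    mask[informative] = 1
    f1 = ev(mask)
    f2 = ev(mask.copy())
    assert f1 == f2
    assert ev.evaluations == 1


def test_chromosome_length_mismatch():
    X, y, _ = _planted()
    ev = FitnessEvaluator(X, y, GaConfig(), AnnConfig(), SplitSpec())
    with pytest.raises(ValueError):
        ev(np.ones(21, dtype=np.uint8))


# ------------------------------------------------------------- full GA
def _tiny_run(seed=0, iterations=5, elitism=True):
    X, y, informative = _planted(seed)
    ga_cfg = GaConfig(population_size=6, iterations=iterations,
                      mutation_prob=0.02, init_one_prob=0.2,
                      elitism=elitism, seed=seed)
    return run_ga(X, y, ga_cfg, AnnConfig(seed=seed, max_epochs=100,
                                          patience=10),
                  SplitSpec(seed=seed)), informative


def test_history_length_equals_iterations():
    res, _ = _tiny_run(iterations=5)
    assert len(res.history) == 5


def test_elitism_makes_max_fitness_monotone():
    res, _ = _tiny_run(iterations=8)
    assert np.all(np.diff(res.max_history) >= 0)
    assert res.best_fitness == res.max_history[-1]


def test_ga_run_is_reproducible():
    r1, _ = _tiny_run(seed=3)
    r2, _ = _tiny_run(seed=3)
    np.testing.assert_array_equal(r1.best_chromosome, r2.best_chromosome)
    assert r1.history == r2.history


def test_planted_recovery_beats_random_selection():
    """On the planted benchmark, the GA concentrates its selections on the
    informative columns far above their base rate (10/200 = 5%)."""
    X, y, informative = generate_planted_features(seed=0)
    fracs = []
    for seed in range(3):
        ga_cfg = GaConfig(population_size=20, iterations=15,
                          mutation_prob=0.01, init_one_prob=0.005,
                          feature_cap=6, fitness_mode="kfold_mean", K=5,
                          fitness_restarts=2, seed=seed)
        ann_cfg = AnnConfig(seed=seed, hidden_units=5, max_epochs=150,
                            patience=10, weight_decay=1e-2)
        res = run_ga(X, y, ga_cfg, ann_cfg, SplitSpec(seed=seed))
        selected = np.where(res.best_chromosome == 1)[0]
        fracs.append(np.isin(selected, informative).mean())
    assert np.mean(fracs) >= 0.25  # >= 5x enrichment over the base rate
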