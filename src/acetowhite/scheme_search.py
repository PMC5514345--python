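"""Evolutionary-programming search over discretization schemes.

The discretization of an acetowhite time series has two coupled knobs: where
the segment boundaries fall along time (variable word sizes) and how many
value intervals the alphabet has.  This module searches both jointly with a
mutation-only evolutionary program: each parent spawns one mutant (perturb a
boundary, insert or delete a boundary, or increment/decrement the alphabet
size), candidates are scored by stratified cross-validated accuracy of the
downstream classifier on the training set under their PLA encoding, and
elitist selection keeps the best ``population_size`` of parents plus
offspring.  Fitness ties break toward fewer segments, then a smaller
alphabet — compression is the point of discretizing at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import KNNClassifier
from .datasets import LabeledDataset
from .evaluation import cross_validate
from .representations import DiscretizationScheme, calibrate_scheme, discretize_pla


@dataclass
class EPConfig:
    population_size: int = 20
    generations: int = 50
    mutation_rate: float = 1.0  # probability each offspring actually mutates
    max_segments: int = 30
    alphabet_range: tuple[int, int] = (2, 10)
    fitness_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be at least 1")
        lo, hi = self.alphabet_range
        if not (2 <= lo <= hi <= 26):
            raise ValueError("alphabet_range must lie within [2, 26]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")


@dataclass
class Candidate:
    scheme: DiscretizationScheme
    fitness: float

    @property
    def n_segments(self) -> int:
        return self.scheme.n_segments

    @property
    def alphabet_size(self) -> int:
        return self.scheme.alphabet_size


@dataclass
class EPLog:
    generations: list = field(default_factory=list)  # (gen, best_fitness)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.generations, columns=["generation", "best_fitness"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _random_boundaries(n_post: int, n_segments: int, rng: np.random.Generator) -> list[int]:
    interior = rng.choice(np.arange(1, n_post), size=n_segments - 1, replace=False)
    return sorted(int(b) for b in interior) + [n_post]


def _mutate_boundaries(
    boundaries: list[int], n_post: int, max_segments: int, rng: np.random.Generator
) -> list[int]:
    interior = boundaries[:-1]
    ops = ["perturb", "insert", "delete"]
    op = ops[rng.integers(len(ops))]
    if op == "perturb" and interior:
        i = int(rng.integers(len(interior)))
        lo = (interior[i - 1] if i > 0 else 0) + 1
        hi = (interior[i + 1] if i + 1 < len(interior) else n_post) - 1
        if lo <= hi:
            interior = list(interior)
            interior[i] = int(rng.integers(lo, hi + 1))
    elif op == "insert" and len(interior) + 1 < max_segments:
        candidates = sorted(set(range(1, n_post)) - set(interior))
        if candidates:
            interior = sorted(interior + [int(candidates[rng.integers(len(candidates))])])
    elif op == "delete" and len(interior) > 1:
        i = int(rng.integers(len(interior)))
        interior = interior[:i] + interior[i + 1 :]
    return sorted(set(interior)) + [n_post]


def scheme_fitness(
    train: LabeledDataset,
    boundaries: list[int],
    alphabet_size: int,
    classifier_factory=None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, DiscretizationScheme]:
    """Cross-validated accuracy of the classifier under a PLA encoding.

    ``train`` holds standardized (continuous) series; the alphabet cuts are
    calibrated on the whole training set by equal-frequency quantiles of
    segment means, then fold-wise accuracy is measured on the symbols.
    """
    if classifier_factory is None:
        classifier_factory = KNNClassifier
    scheme = calibrate_scheme(train.features, boundaries, alphabet_size)
    symbols = np.vstack([discretize_pla(row, scheme).symbols for row in train.features])
    encoded = LabeledDataset(
        symbols, train.labels, "pla", discrete=True, case_ids=list(train.case_ids)
    )
    cv = cross_validate(encoded, classifier_factory, k=folds, seed=seed)
    return cv.confusion.accuracy, scheme


def evolve_scheme(
    train: LabeledDataset,
    classifier_factory=None,
    config: EPConfig | None = None,
) -> tuple[Candidate, EPLog]:
    """Evolve boundaries and alphabet size maximizing training CV accuracy.

    Deterministic given ``config.seed``.  The best candidate's fitness is
    monotone non-decreasing across generations (elitism), and every emitted
    scheme tiles the series with non-empty segments.
    """
    if config is None:
        config = EPConfig()
    if len(train) == 0:
        raise ValueError("empty training set")
    n_post = train.n_features
    rng = np.random.default_rng(config.seed)
    lo, hi = config.alphabet_range
    max_segments = min(config.max_segments, n_post)

    def evaluate(boundaries: list[int], alphabet: int) -> Candidate:
        fit, scheme = scheme_fitness(
            train,
            boundaries,
            alphabet,
            classifier_factory,
            folds=config.fitness_folds,
            seed=config.seed,
        )
        return Candidate(scheme=scheme, fitness=fit)

    population: list[Candidate] = []
    for _ in range(config.population_size):
        n_seg = int(rng.integers(2, max_segments + 1))
        alphabet = int(rng.integers(lo, hi + 1))
        population.append(evaluate(_random_boundaries(n_post, n_seg, rng), alphabet))

    def sort_key(c: Candidate):
        return (-c.fitness, c.n_segments, c.alphabet_size)

    population.sort(key=sort_key)
    log = EPLog()
    log.generations.append((0, population[0].fitness))

    for gen in range(1, config.generations + 1):
        offspring = []
        for parent in population:
            boundaries = list(parent.scheme.boundaries)
            alphabet = parent.alphabet_size
            if rng.random() < config.mutation_rate:
                if rng.random() < 0.5:
                    boundaries = _mutate_boundaries(boundaries, n_post, max_segments, rng)
                else:
                    alphabet = int(np.clip(alphabet + rng.choice([-1, 1]), lo, hi))
            offspring.append(evaluate(boundaries, alphabet))
        population = sorted(population + offspring, key=sort_key)[: config.population_size]
        log.generations.append((gen, population[0].fitness))

    return population[0], log
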