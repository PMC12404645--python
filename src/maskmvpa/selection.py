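"""Genetic-algorithm stimulus subset selection.

When stimuli are drawn from natural images, responses at the entry and
endpoint of the ventral visual hierarchy tend to be highly correlated,
which confounds attempts to attribute multivariate effects to a
processing stage.  Given two reference RDMs over a candidate stimulus
pool (e.g. early visual cortex and inferior temporal cortex), the GA
searches for the size-k subset whose restricted sub-RDMs have minimal
absolute rank correlation, so that the two stages are representationally
dissociable for the chosen stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = ["SubsetResult", "genetic_subset", "subset_objective", "random_baseline"]


@dataclass
class SubsetResult:
    """Chosen subset with its objective and per-generation history."""

    indices: np.ndarray
    objective: float
    history: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, int)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("indices must be unique")


def subset_objective(
    rdm_a: np.ndarray, rdm_b: np.ndarray, indices: np.ndarray
) -> float:
    """|Spearman correlation| between the two RDMs restricted to ``indices``."""
    idx = np.asarray(indices, int)
    sub_a = rdm_a[np.ix_(idx, idx)]
    sub_b = rdm_b[np.ix_(idx, idx)]
    i, j = np.tril_indices(idx.size, k=-1)
    r = sp_stats.spearmanr(sub_a[i, j], sub_b[i, j]).statistic
    return abs(float(r))


def random_baseline(
    rdm_a: np.ndarray, rdm_b: np.ndarray, k: int, n_draws: int,
    rng: np.random.Generator,
) -> float:
    """Best (lowest) objective over ``n_draws`` uniformly random subsets."""
    n = rdm_a.shape[0]
    return min(
        subset_objective(rdm_a, rdm_b, rng.choice(n, size=k, replace=False))
        for _ in range(n_draws)
    )


def _repair(member: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Force a boolean membership vector back to exactly k selected items."""
    on = np.flatnonzero(member)
    off = np.flatnonzero(~member)
    if on.size > k:
        member[rng.choice(on, size=on.size - k, replace=False)] = False
    elif on.size < k:
        member[rng.choice(off, size=k - on.size, replace=False)] = True
    return member


def genetic_subset(
    rdm_a: np.ndarray,
    rdm_b: np.ndarray,
    k: int,
    population: int = 200,
    generations: int = 500,
    mutation_rate: float = 0.02,
    rng: np.random.Generator | int | None = None,
    elite: int = 2,
    tournament: int = 3,
) -> SubsetResult:
    """Minimise |Spearman| between sub-RDMs over size-``k`` subsets.

    Individuals are boolean membership vectors; parents are chosen by
    tournament selection, recombined by uniform crossover, bit-flip
    mutated at ``mutation_rate``, and repaired back to exactly ``k``
    members.  The best ``elite`` individuals survive unchanged, so the
    best objective in ``history`` is non-increasing.
    """
    rng = np.random.default_rng(rng)
    rdm_a = np.asarray(rdm_a, float)
    rdm_b = np.asarray(rdm_b, float)
    n = rdm_a.shape[0]
    if rdm_a.shape != (n, n) or rdm_b.shape != (n, n):
        raise ValueError("RDMs must be square and equally sized")
    if k >= n:
        raise ValueError(f"subset size k={k} must be smaller than K={n}")
    if k < 4:
        raise ValueError("k must be >= 4 for a meaningful sub-RDM correlation")

    def score(member: np.ndarray) -> float:
        return subset_objective(rdm_a, rdm_b, np.flatnonzero(member))

    pop = np.zeros((population, n), dtype=bool)
    for i in range(population):
        pop[i, rng.choice(n, size=k, replace=False)] = True
    fitness = np.array([score(m) for m in pop])

    history = []
    elite = min(elite, population)
    for _ in range(generations):
        best_order = np.argsort(fitness)
        history.append(fitness[best_order[0]])
        new_pop = [pop[i].copy() for i in best_order[:elite]]
        while len(new_pop) < population:
            picks = rng.integers(0, population, size=(2, tournament))
            pa = pop[picks[0][np.argmin(fitness[picks[0]])]]
            pb = pop[picks[1][np.argmin(fitness[picks[1]])]]
            mix = rng.random(n) < 0.5
            child = np.where(mix, pa, pb)
            flip = rng.random(n) < mutation_rate
            child = child ^ flip
            new_pop.append(_repair(child, k, rng))
        pop = np.array(new_pop)
        fitness = np.array([score(m) for m in pop])

    best = int(np.argmin(fitness))
    history.append(fitness[best])
    # elitism guarantees monotone history; enforce by running minimum
    history = np.minimum.accumulate(history)
    return SubsetResult(
        indices=np.flatnonzero(pop[best]),
        objective=float(fitness[best]),
        history=np.asarray(history),
    )
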