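"""Genetic-algorithm feature selection with joint SVM cost tuning.

The chromosome carries one binary gene per meta-feature column plus a
3-bit parametric gene encoding the SVM cost C. The bits are read
most-significant first and mapped through ``value mod 6`` onto the cost
grid {1, 2, 4, 8, 16, 32}; the two surplus patterns (110, 111) therefore
wrap onto C = 1 and C = 2, keeping mutation closed over the genotype
space. Fitness is the mean cross-validated Matthews correlation
coefficient (MCC) of an RBF-kernel SVM with cost C trained on the masked
columns; the feature set with the highest MCC wins, with ties broken
toward fewer selected features and then a smaller C (parsimony).

The search itself is a standard generational GA — tournament selection
(size 2), uniform crossover, per-gene bit-flip mutation, one elite —
followed by a single-bit-flip hill-climbing pass on the best chromosome.
Fold assignment for fitness evaluation is seeded independently of the
evolution randomness and fixed for a whole run, so fitness values are
memoised per (mask, C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .baselines import derive_seed
from .metrics import confusion, mcc_from_counts

logger = logging.getLogger(__name__)

#: Allowed SVM cost values, indexed by the decoded 3-bit gene mod 6.
C_GRID: tuple[int, ...] = (1, 2, 4, 8, 16, 32)


@dataclass
class Chromosome:
    """Binary feature-selection genes plus a 3-bit cost gene."""

    feature_genes: np.ndarray  # shape (n,), values in {0, 1}
    param_genes: np.ndarray    # shape (3,), values in {0, 1}, MSB first

    def copy(self) -> "Chromosome":
        return Chromosome(self.feature_genes.copy(), self.param_genes.copy())


def decode_chromosome(
    ch: Chromosome, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """Decode to (boolean feature mask, C).

    An all-zero mask is repaired in place by activating one uniformly
    random gene (seeded generator), with a logged warning. Total over all
    8 parametric bit patterns.
    """
    genes = np.asarray(ch.feature_genes)
    if not genes.any():
        rng = rng if rng is not None else np.random.default_rng(0)
        idx = int(rng.integers(genes.size))
        ch.feature_genes[idx] = 1
        logger.warning("all-zero feature mask repaired: activated gene %d", idx)
    b = np.asarray(ch.param_genes)
    value = int(4 * b[0] + 2 * b[1] + b[2])
    return ch.feature_genes.astype(bool), C_GRID[value % 6]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/(n_genes)
    elitism: int = 1
    seed: int = 0
    fitness_folds: int = 10

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for r in (self.crossover_rate,) + (
            (self.mutation_rate,) if self.mutation_rate is not None else ()
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.elitism <= self.population_size:
            raise ValueError("elitism must be within the population size")


@dataclass
class GAResult:
    best_chromosome: Chromosome
    best_fitness: float
    history: list[float]
    selected_names: list[str]
    selected_mask: np.ndarray
    C: int
    seed: int
    final_population: list[Chromosome] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "best_fitness": self.best_fitness,
            "selected_names": self.selected_names,
            "selected_mask": self.selected_mask.astype(int).tolist(),
            "C": self.C,
            "history": self.history,
            "seed": self.seed,
        }


def fitness(
    ch: Chromosome,
    M: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean k-fold cross-validated MCC of an RBF SVM on the masked columns.

    A fold whose test part holds a single class contributes MCC 0 (and is
    logged). Deterministic given (chromosome, M, y, k, seed).
    """
    mask, C = decode_chromosome(ch)
    return _masked_svm_cv_mcc(np.asarray(M, dtype=float), np.asarray(y), mask, C, k, seed)


def _masked_svm_cv_mcc(
    M: np.ndarray, y: np.ndarray, mask: np.ndarray, C: int, k: int, seed: int
) -> float:
    X = M[:, mask]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    per_fold = []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[test_idx])) < 2:
            logger.debug("single-class test fold; MCC counted as 0")
            per_fold.append(0.0)
            continue
        clf = SVC(kernel="rbf", C=C, gamma="scale")
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        per_fold.append(mcc_from_counts(confusion(y[test_idx], pred)))
    return float(np.mean(per_fold))


def _key(fit: float, mask: np.ndarray, C: int) -> tuple[float, int, int]:
    """Lexicographic maximization key: fitness, then parsimony, then low C."""
    return (fit, -int(mask.sum()), -C)


def exhaustive_best_fitness(
    M: np.ndarray | pd.DataFrame, y: np.ndarray, k: int = 10, seed: int = 0
) -> float:
    """Brute-force maximum fitness over every non-empty mask and every C.

    Only feasible for small column counts; used as an optimality oracle.
    """
    M = np.asarray(M, dtype=float)
    y = np.asarray(y)
    n = M.shape[1]
    best = -np.inf
    for bits in range(1, 2**n):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        for C in C_GRID:
            best = max(best, _masked_svm_cv_mcc(M, y, mask, C, k, seed))
    return best


def run_ga_sar(
    M: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    cfg: GAConfig | None = None,
) -> GAResult:
    """Evolve a feature mask and SVM cost maximizing cross-validated MCC.

    Returns the best-ever chromosome after a final single-bit-flip
    refinement pass; ``history`` records the best-so-far fitness per
    generation and is non-decreasing.
    """
    cfg = cfg or GAConfig()
    if isinstance(M, pd.DataFrame):
        names = list(M.columns)
        M_arr = M.to_numpy(dtype=float)
    else:
        M_arr = np.asarray(M, dtype=float)
        names = [f"f{i}" for i in range(M_arr.shape[1])]
    y = np.asarray(y)
    if M_arr.ndim != 2 or M_arr.shape[1] < 1:
        raise ValueError("M must be 2-D with at least one column")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    n = M_arr.shape[1]
    n_genes = n + 3
    mu = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_genes

    rng = np.random.default_rng(derive_seed(cfg.seed, "evolution"))
    fit_seed = derive_seed(cfg.seed, "fitness")
    cache: dict[tuple[bytes, int], float] = {}

    def evaluate(ch: Chromosome) -> tuple[float, np.ndarray, int]:
        mask, C = decode_chromosome(ch, rng)
        key = (np.packbits(mask).tobytes(), C)
        if key not in cache:
            cache[key] = _masked_svm_cv_mcc(
                M_arr, y, mask, C, cfg.fitness_folds, fit_seed
            )
        return cache[key], mask, C

    def genome_to_ch(g: np.ndarray) -> Chromosome:
        return Chromosome(g[:n].copy(), g[n:].copy())

    population = [
        genome_to_ch(rng.integers(0, 2, size=n_genes).astype(np.int64))
        for _ in range(cfg.population_size)
    ]
    scored = [evaluate(ch) for ch in population]

    best_ch: Chromosome | None = None
    best_eval: tuple[float, np.ndarray, int] | None = None

    def consider(ch: Chromosome, ev: tuple[float, np.ndarray, int]) -> None:
        nonlocal best_ch, best_eval
        if best_eval is None or _key(ev[0], ev[1], ev[2]) > _key(
            best_eval[0], best_eval[1], best_eval[2]
        ):
            best_ch, best_eval = ch.copy(), ev

    for ch, ev in zip(population, scored):
        consider(ch, ev)
    history: list[float] = []

    def tournament() -> Chromosome:
        i, j = rng.integers(cfg.population_size, size=2)
        ki = _key(scored[i][0], scored[i][1], scored[i][2])
        kj = _key(scored[j][0], scored[j][1], scored[j][2])
        return population[i if ki >= kj else j]

    for _gen in range(cfg.generations):
        order = sorted(
            range(cfg.population_size),
            key=lambda i: _key(scored[i][0], scored[i][1], scored[i][2]),
            reverse=True,
        )
        elites = [population[i].copy() for i in order[: cfg.elitism]]
        children: list[Chromosome] = []
        while len(children) < cfg.population_size - cfg.elitism:
            p1, p2 = tournament(), tournament()
            g1 = np.concatenate([p1.feature_genes, p1.param_genes])
            g2 = np.concatenate([p2.feature_genes, p2.param_genes])
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(n_genes) < 0.5
                g1, g2 = np.where(swap, g2, g1), np.where(swap, g1, g2)
            for g in (g1, g2):
                flip = rng.random(n_genes) < mu
                g = np.where(flip, 1 - g, g)
                children.append(genome_to_ch(g.astype(np.int64)))
        population = elites + children[: cfg.population_size - cfg.elitism]
        scored = [evaluate(ch) for ch in population]
        for ch, ev in zip(population, scored):
            consider(ch, ev)
        history.append(best_eval[0])

    # Local refinement: accept single-bit flips that improve the
    # (fitness, parsimony, low-C) key, restarting until a local optimum.
    improved = True
    while improved:
        improved = False
        base = np.concatenate([best_ch.feature_genes, best_ch.param_genes])
        for i in range(n_genes):
            g = base.copy()
            g[i] = 1 - g[i]
            cand = genome_to_ch(g)
            if not cand.feature_genes.any():
                continue
            ev = evaluate(cand)
            if _key(ev[0], ev[1], ev[2]) > _key(
                best_eval[0], best_eval[1], best_eval[2]
            ):
                best_ch, best_eval = cand, ev
                improved = True
                break

    fit_val, mask, C = best_eval
    return GAResult(
        best_chromosome=best_ch,
        best_fitness=float(fit_val),
        history=history,
        selected_names=[names[i] for i in np.flatnonzero(mask)],
        selected_mask=mask,
        C=C,
        seed=cfg.seed,
        final_population=[ch.copy() for ch in population],
    )
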