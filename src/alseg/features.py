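"""Feature construction and model selection.

Predictors are built from the image bands as *terms*: main effects ("j")
or two-way interactions ("j:k", the elementwise product of two bands).
Each term can optionally be expanded in a piecewise-linear (triangular
"tent") basis on [0, 1], giving an additive model in the conditional
logit.  Subset selection over a pool of candidate terms is done with a
fixed-size genetic algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .lattice import DesignMatrix

__all__ = [
    "TriangularBasisSpec",
    "triangular_basis",
    "Term",
    "parse_term",
    "main_effects",
    "all_terms",
    "build_design",
    "GaConfig",
    "ga_select",
    "model_search",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TriangularBasisSpec:
    """Piecewise-linear tent basis with equally spaced knots on [0, 1].

    The ``n_basis`` functions form a partition of unity: at every x in
    [0, 1] the basis values sum to 1, with at most two nonzero.
    """

    n_basis: int = 6

    def __post_init__(self) -> None:
        if self.n_basis < 2:
            raise ValueError("at least two basis functions are required")

    @property
    def knots(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_basis)


def triangular_basis(x: np.ndarray, spec: TriangularBasisSpec | None = None) -> np.ndarray:
    """Evaluate the tent basis at ``x``; values outside [0, 1] are clipped.

    Returns an ``(n, n_basis)`` matrix whose rows sum to 1.  The number of
    clipped inputs is logged.
    """
    spec = spec or TriangularBasisSpec()
    x = np.asarray(x, dtype=float).ravel()
    n_clipped = int(np.sum((x < 0) | (x > 1)))
    if n_clipped:
        log.info("triangular_basis: clipped %d value(s) to [0, 1]", n_clipped)
        x = np.clip(x, 0.0, 1.0)
    knots = spec.knots
    h = knots[1] - knots[0]
    B = np.maximum(0.0, 1.0 - np.abs(x[:, None] - knots[None, :]) / h)
    B[B < 1e-12] = 0.0  # drop float crumbs so each row has <= 2 true supports
    return B


@dataclass(frozen=True, order=True)
class Term:
    """A main effect ``(j,)`` or interaction ``(j, k)`` with ``j < k``."""

    bands: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bands) not in (1, 2):
            raise ValueError("a term has one band or two")
        if len(self.bands) == 2 and not self.bands[0] < self.bands[1]:
            raise ValueError("interaction terms must have bands ordered j < k")
        if any(b < 0 for b in self.bands):
            raise ValueError("band indices must be non-negative")

    @property
    def label(self) -> str:
        return ":".join(str(b) for b in self.bands)

    def values(self, flat: np.ndarray) -> np.ndarray:
        """Evaluate the term on an ``(n, k)`` matrix of band values."""
        k = flat.shape[1]
        if any(b >= k for b in self.bands):
            raise ValueError(f"term {self.label!r} references a band beyond the {k} available")
        if len(self.bands) == 1:
            return flat[:, self.bands[0]]
        return flat[:, self.bands[0]] * flat[:, self.bands[1]]


def parse_term(text: str) -> Term:
    """Parse ``"j"`` or ``"j:k"`` notation into a :class:`Term`."""
    parts = tuple(int(p) for p in text.split(":"))
    return Term(parts)


def main_effects(n_bands: int) -> list[Term]:
    return [Term((j,)) for j in range(n_bands)]


def all_terms(n_bands: int) -> list[Term]:
    """All main effects plus all two-way interactions."""
    terms = main_effects(n_bands)
    terms += [Term((j, k)) for j in range(n_bands) for k in range(j + 1, n_bands)]
    return terms


def build_design(
    stack: np.ndarray,
    terms: Sequence[Term],
    basis: TriangularBasisSpec | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix for a set of terms.

    Without a basis: the raw term values (plus intercept).  With a basis:
    one global intercept plus, per term, the basis expansion of the term's
    value with the first basis column dropped, i.e. ``n_basis - 1``
    coefficients per term.  Dropping one column per term removes the
    confounding with the intercept (the basis is a partition of unity).
    """
    if len({t.label for t in terms}) != len(terms):
        raise ValueError("duplicate terms in the term set")
    v = np.asarray(stack, dtype=float)
    flat = v.reshape(-1, v.shape[-1])
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(flat)))
        names.append("intercept")
    for t in terms:
        tv = t.values(flat)
        if basis is None:
            cols.append(tv)
            names.append(t.label)
        else:
            B = triangular_basis(tv, basis)[:, 1:]
            for j in range(B.shape[1]):
                cols.append(B[:, j])
                names.append(f"{t.label}_b{j + 1}")
    return DesignMatrix(np.column_stack(cols), columns=tuple(names), intercept=intercept)


@dataclass(frozen=True)
class GaConfig:
    population: int = 100
    generations: int = 150
    tournament: int = 3
    mutation_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.population, self.generations, self.tournament) < 1:
            raise ValueError("population, generations and tournament must be positive")
        if not 0.0 < self.mutation_rate < 1.0:
            raise ValueError("mutation rate must be in (0, 1)")


def ga_select(
    pool: Sequence[Term],
    k: int,
    objective: Callable[[tuple[Term, ...]], float],
    cfg: GaConfig | None = None,
) -> tuple[tuple[Term, ...], list[float]]:
    """Fixed-size-k subset search by genetic algorithm (lower objective wins).

    Tournament selection, subset-union crossover with repair back to size k,
    and element-swap mutation; the best individual is carried over unchanged
    (elitism), so the result is never worse than the best of the initial
    population.  Deterministic for a given ``cfg.seed``.  Returns the best
    subset found (sorted) and the best-objective trace per generation.
    """
    cfg = cfg or GaConfig()
    pool = list(pool)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    if k == len(pool):
        subset = tuple(sorted(pool))
        return subset, [objective(subset)]
    rng = np.random.default_rng(cfg.seed)
    pool_idx = np.arange(len(pool))
    cache: dict[frozenset, float] = {}

    def score(ind: frozenset) -> float:
        if ind not in cache:
            cache[ind] = float(objective(tuple(sorted(pool[i] for i in ind))))
        return cache[ind]

    popn = [frozenset(rng.choice(pool_idx, size=k, replace=False)) for _ in range(cfg.population)]
    fitness = [score(ind) for ind in popn]
    trace = [min(fitness)]

    def tournament() -> frozenset:
        contenders = rng.integers(0, len(popn), size=cfg.tournament)
        best = min(contenders, key=lambda i: fitness[i])
        return popn[best]

    for _ in range(cfg.generations):
        order = int(np.argmin(fitness))
        new_pop = [popn[order]]  # elitism
        while len(new_pop) < cfg.population:
            p1, p2 = tournament(), tournament()
            union = np.fromiter(p1 | p2, dtype=int)
            child = set(rng.choice(union, size=k, replace=False))
            # swap mutation: exchange members for non-members
            for _ in range(k):
                if rng.random() < cfg.mutation_rate:
                    out = rng.choice(np.fromiter(child, dtype=int))
                    avail = np.setdiff1d(pool_idx, np.fromiter(child, dtype=int))
                    child.discard(int(out))
                    child.add(int(rng.choice(avail)))
            new_pop.append(frozenset(child))
        popn = new_pop
        fitness = [score(ind) for ind in popn]
        trace.append(min(fitness))
    best = popn[int(np.argmin(fitness))]
    return tuple(sorted(pool[i] for i in best)), trace


def model_search(
    pool: Sequence[Term],
    sizes: Sequence[int],
    objective: Callable[[tuple[Term, ...]], float],
    cfg: GaConfig | None = None,
) -> dict:
    """Run :func:`ga_select` at each model size; return per-size bests and
    the overall minimizer of the objective."""
    if any(s < 1 for s in sizes):
        raise ValueError("model sizes must be positive")
    cfg = cfg or GaConfig()
    results = {}
    for i, k in enumerate(sizes):
        sub_cfg = GaConfig(
            cfg.population,
            cfg.generations,
            cfg.tournament,
            cfg.mutation_rate,
            None if cfg.seed is None else cfg.seed + i,
        )
        subset, trace = ga_select(pool, k, objective, sub_cfg)
        results[k] = {"terms": subset, "objective": trace[-1], "trace": trace}
    best_size = min(results, key=lambda s: results[s]["objective"])
    return {"per_size": results, "best_size": best_size, "best": results[best_size]}
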