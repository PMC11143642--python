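"""NSGA-II dose optimization over the fitted surrogates.

Four objectives — leaf number, proliferation rate, explant survival and
shoot length, each predicted by one surrogate — are maximized jointly over
the experimental dose rectangle GA3 in [0, 0.5] x ZT in [0, 0.75] mg/L.
The evolutionary loop is real-coded NSGA-II: binary tournament selection on
(front rank, crowding distance), simulated binary crossover (SBX), and
polynomial mutation. A single compromise solution is then selected from the
final non-dominated front as the point closest (after per-objective min-max
normalization over the front) to the ideal point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("culturopt")

OBJECTIVE_NAMES = ("LN", "PR", "ES", "SL")


@dataclass(frozen=True)
class OptimizerConfig:
    population: int = 100
    generations: int = 200
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0
    ga3_bounds: tuple[float, float] = (0.0, 0.5)
    zt_bounds: tuple[float, float] = (0.0, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class ParetoSolution:
    ga3: float
    zt: float
    predicted: dict[str, float]
    front_rank: int
    crowding: float

    def objectives(self) -> np.ndarray:
        return np.array([self.predicted[k] for k in OBJECTIVE_NAMES])


# ---------------------------------------------------------------------------
# Dominance primitives (independent of the evolutionary loop)

def nondominated_sort(points: np.ndarray, sense: str = "maximize") -> list[list[int]]:
    """Fast non-dominated sorting; front 1 first, every index exactly once."""
    F = np.asarray(points, float)
    if F.size == 0:
        return []
    F = np.atleast_2d(F)
    if sense == "minimize":
        F = -F
    elif sense != "maximize":
        raise ValueError("sense must be 'maximize' or 'minimize'")
    n = len(F)
    # dominates[i, j]: i weakly better on all objectives, strictly on one
    ge = np.all(F[:, None, :] >= F[None, :, :], axis=2)
    gt = np.any(F[:, None, :] > F[None, :, :], axis=2)
    dom = ge & gt
    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    remaining = np.arange(n)
    counts = n_dominators.copy()
    assigned = np.zeros(n, bool)
    while not assigned.all():
        current = [int(i) for i in remaining if not assigned[i] and counts[i] == 0]
        if not current:  # numerical safety; cannot occur with a strict partial order
            current = [int(i) for i in remaining if not assigned[i]]
        fronts.append(current)
        assigned[current] = True
        for i in current:
            counts[dom[i]] -= 1
    return fronts


def crowding_distance(front: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance for one front of objective vectors.

    Boundary points per objective get infinity; interior points accumulate
    the normalized gap between their neighbors; a degenerate objective
    (max = min) contributes nothing. Fronts of size <= 2 are all infinite.
    """
    F = np.atleast_2d(np.asarray(front, float))
    n, m = F.shape
    if n == 0:
        raise ValueError("empty front")
    if n <= 2:
        return np.full(n, np.inf)
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / span
            d[order[1:-1]] += gaps
    return d


# ---------------------------------------------------------------------------
# Variation operators

def _sbx(parents: np.ndarray, lo: np.ndarray, hi: np.ndarray, prob: float,
         eta: float, rng: np.random.Generator) -> np.ndarray:
    """Simulated binary crossover on consecutive parent pairs."""
    child = parents.copy()
    for i in range(0, len(parents) - 1, 2):
        if rng.random() > prob:
            continue
        p1, p2 = parents[i].copy(), parents[i + 1].copy()
        for j in range(parents.shape[1]):
            if rng.random() > 0.5:
                continue
            u = rng.random()
            beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (
                1 / (2 * (1 - u))) ** (1 / (eta + 1))
            c1 = 0.5 * ((1 + beta) * p1[j] + (1 - beta) * p2[j])
            c2 = 0.5 * ((1 - beta) * p1[j] + (1 + beta) * p2[j])
            child[i, j], child[i + 1, j] = c1, c2
    return np.clip(child, lo, hi)


def _polynomial_mutation(pop: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                         eta: float, rng: np.random.Generator) -> np.ndarray:
    """Real-valued polynomial mutation, per-variable probability 1/n_var."""
    out = pop.copy()
    n, m = pop.shape
    p_mut = 1.0 / m
    for i in range(n):
        for j in range(m):
            if rng.random() > p_mut:
                continue
            x = out[i, j]
            span = hi[j] - lo[j]
            d1 = (x - lo[j]) / span
            d2 = (hi[j] - x) / span
            u = rng.random()
            if u <= 0.5:
                delta = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1)) ** (1 / (eta + 1)) - 1
            else:
                delta = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1)) ** (
                    1 / (eta + 1))
            out[i, j] = x + delta * span
    return np.clip(out, lo, hi)


def _tournament(ranks: np.ndarray, crowd: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Binary tournament on (rank, crowding); returns selected indices."""
    n = len(ranks)
    cand = rng.integers(n, size=(n, 2))
    a, b = cand[:, 0], cand[:, 1]
    a_wins = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] > crowd[b]))
    return np.where(a_wins, a, b)


def run_nsga2(
    objective_fn: Callable[[np.ndarray], np.ndarray],
    config: OptimizerConfig,
    callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> list[ParetoSolution]:
    """Evolve dose pairs maximizing ``objective_fn`` (vectorized, (n,2)->(n,4)).

    Returns the final rank-1 set with predictions and crowding distances;
    the returned front is re-verified non-dominated with this module's own
    sorting primitive."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9A2]))
    lo = np.array([config.ga3_bounds[0], config.zt_bounds[0]])
    hi = np.array([config.ga3_bounds[1], config.zt_bounds[1]])
    n = config.population

    pop = lo + rng.random((n, 2)) * (hi - lo)
    F = np.atleast_2d(objective_fn(pop))

    def rank_crowd(objs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fronts = nondominated_sort(objs, "maximize")
        ranks = np.empty(len(objs), int)
        crowd = np.empty(len(objs))
        for r, front in enumerate(fronts, start=1):
            ranks[front] = r
            crowd[front] = crowding_distance(objs[front])
        return ranks, crowd

    ranks, crowd = rank_crowd(F)
    for _gen in range(config.generations):
        parents = pop[_tournament(ranks, crowd, rng)]
        off = _sbx(parents, lo, hi, config.crossover_prob, config.crossover_eta, rng)
        off = _polynomial_mutation(off, lo, hi, config.mutation_eta, rng)
        F_off = np.atleast_2d(objective_fn(off))

        merged = np.vstack([pop, off])
        F_merged = np.vstack([F, F_off])
        fronts = nondominated_sort(F_merged, "maximize")
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= n:
                keep.extend(front)
            else:
                cd = crowding_distance(F_merged[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(int(front[i]) for i in order[: n - len(keep)])
                break
        keep_arr = np.asarray(keep, int)
        pop, F = merged[keep_arr], F_merged[keep_arr]
        ranks, crowd = rank_crowd(F)
        if callback is not None:
            callback(_gen, pop, F)

    front_idx = np.where(ranks == 1)[0]
    # drop duplicate dose pairs, keeping first occurrence
    _, uniq = np.unique(np.round(pop[front_idx], 12), axis=0, return_index=True)
    front_idx = front_idx[np.sort(uniq)]
    cd = crowding_distance(F[front_idx])

    # Own-oracle verification of the returned front.
    check = nondominated_sort(F[front_idx], "maximize")
    if len(check) != 1:
        raise RuntimeError("internal error: returned front contains dominated points")

    return [
        ParetoSolution(
            ga3=float(pop[i, 0]), zt=float(pop[i, 1]),
            predicted={k: float(v) for k, v in zip(OBJECTIVE_NAMES, F[i])},
            front_rank=1, crowding=float(c),
        )
        for i, c in zip(front_idx, cd)
    ]


def surrogate_objectives(surrogates: dict[str, object]) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized 4-objective function from one surrogate per trait.

    Survival predictions are clipped to [0, 100] before any dominance
    comparison (predict's report-time clipping handles this)."""
    from .model_zoo import predict

    missing = set(OBJECTIVE_NAMES) - set(surrogates)
    if missing:
        raise ValueError(f"missing surrogate(s) for trait(s) {sorted(missing)}")

    def objective_fn(doses: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [predict(surrogates[t], doses, clip=True) for t in OBJECTIVE_NAMES]
        )

    return objective_fn


def select_compromise(front: Sequence[ParetoSolution]) -> ParetoSolution:
    """Single reported solution: minimize Euclidean distance to the ideal
    point after min-max normalizing each objective over the front.

    Ties are broken by higher crowding distance, then lowest (ga3, zt)
    lexicographically. This selection rule is this package's own convention.
    """
    if not front:
        raise ValueError("empty front")
    if len(front) == 1:
        return front[0]
    F = np.array([s.objectives() for s in front])
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = np.where(hi > lo, (F - lo) / span, 1.0)
    dist = np.sqrt(((1.0 - norm) ** 2).sum(axis=1))
    best = np.min(dist)
    tied = [i for i in range(len(front)) if np.isclose(dist[i], best, atol=1e-12)]
    if len(tied) > 1:
        logger.info("select_compromise: %d tied solutions, applying tie-break", len(tied))
        tied.sort(key=lambda i: (-front[i].crowding, front[i].ga3, front[i].zt))
    return front[tied[0]]


def front_to_frame(front: Sequence[ParetoSolution]) -> pd.DataFrame:
    rows = [
        {"ga3_mg_per_L": s.ga3, "zt_mg_per_L": s.zt,
         **{f"pred_{k}": s.predicted[k] for k in OBJECTIVE_NAMES},
         "front_rank": s.front_rank, "crowding": s.crowding}
        for s in front
    ]
    return pd.DataFrame(rows)


def write_optimum(solution: ParetoSolution, path: str | Path, seed: int,
                  rule: str = "min_distance_to_ideal_point") -> None:
    payload = {
        "ga3_mg_per_L": solution.ga3, "zt_mg_per_L": solution.zt,
        "predicted": solution.predicted, "selection_rule": rule, "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
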