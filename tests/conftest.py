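import numpy as np
import pytest

from culturopt import generate, load_treatment_stats


@pytest.fixture(scope="session")
def stats():
    return load_treatment_stats()


@pytest.fixture(scope="session")
def full_table(stats):
    """A full 960-row regenerated dataset (all cultivars, 20 replicates)."""
    return generate(stats, seed=1, n_rep=20)


@pytest.fixture(scope="session")
def small_table(stats):
    """A light-weight table for pipeline mechanics tests."""
    return generate(stats, seed=7, n_rep=5, cultivars=("Atabaki",))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the implementations they check)

def brute_force_fronts(points: np.ndarray) -> list[list[int]]:
    """O(n^2 m) non-dominated sorting by repeated scanning (maximization)."""
    F = np.atleast_2d(np.asarray(points, float))
    remaining = list(range(len(F)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if j == i:
                    continue
                if np.all(F[j] >= F[i]) and np.any(F[j] > F[i]):
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


def brute_force_crowding(front: np.ndarray) -> np.ndarray:
    """Textbook per-objective crowding distance, computed objective by objective."""
    F = np.atleast_2d(np.asarray(front, float))
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    d = np.zeros(n)
    for j in range(m):
        order = sorted(range(n), key=lambda i: F[i, j])
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span == 0:
            continue
        for k in range(1, n - 1):
            d[order[k]] += (F[order[k + 1], j] - F[order[k - 1], j]) / span
    return d


def hypervolume_2d(front: np.ndarray, ref: np.ndarray) -> float:
    """Exact 2-objective hypervolume (maximization) w.r.t. a reference point."""
    F = np.atleast_2d(np.asarray(front, float))
    pts = F[np.all(F >= ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    pts = pts[np.argsort(-pts[:, 0])]
    hv, y_prev = 0.0, ref[1]
    for x, y in pts:
        if y > y_prev:
            hv += (x - ref[0]) * (y - y_prev)
            y_prev = y
    return hv
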