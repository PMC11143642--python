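"""Sequential Bayesian hyperparameter search with K-fold cross-validation.

The sampler is a tree-structured Parzen estimator (TPE): after a short
random warm-up, the evaluation history is split at the gamma-quantile of
the objective into "good" and "bad" configurations, each dimension is
modelled by a Parzen (Gaussian-mixture) density over each group, candidate
points are drawn from the good density and the one maximizing the density
ratio l(x)/g(x) is evaluated next. Integer dimensions are quantized at the
sampling step. Everything is driven by one seeded generator, and the
evaluation sequence for budget B is a prefix of the sequence for any larger
budget under the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from .model_zoo import SPACES, Dimension, HyperparameterSpace, fit

logger = logging.getLogger("culturopt")

#: Fraction of the history treated as "good" when building the Parzen split.
TPE_GAMMA = 0.25
#: Candidate draws per TPE proposal.
TPE_N_CANDIDATES = 24
#: Random warm-up evaluations before the Parzen split is used.
TPE_N_STARTUP = 10


@dataclass(frozen=True)
class TuningConfig:
    budget: int = 100
    K: int = 10
    objective: str = "cv_rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.K < 2:
            raise ValueError("K must be >= 2")


@dataclass
class TuningResult:
    best_hyperparams: dict[str, Any]
    best_objective: float
    history: list[tuple[dict[str, Any], float]] = field(repr=False)
    budget_used: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "best_hyperparams": self.best_hyperparams,
            "best_objective": self.best_objective,
            "budget_used": self.budget_used,
            "history": [{"hyperparams": h, "objective": o} for h, o in self.history],
        }
        Path(path).write_text(json.dumps(payload, default=float))


def make_positional_folds(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Balanced random partition of range(n) into K folds (sizes differ <= 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    perm = rng.permutation(n)
    sizes = np.full(K, n // K)
    sizes[: n % K] += 1
    folds, pos = [], 0
    for s in sizes:
        folds.append(np.sort(perm[pos : pos + s]))
        pos += s
    return folds


def cv_objective(
    model_kind: str,
    hyperparams: dict[str, Any],
    X: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    seed: int = 0,
) -> float:
    """Mean held-out-fold RMSE over the K folds."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if any(len(f) < 1 for f in folds):
        raise ValueError("fold with no validation rows")
    rmses = []
    for val_idx in folds:
        fit_idx = np.setdiff1d(np.arange(len(X)), val_idx)
        model = fit(model_kind, hyperparams, X[fit_idx], y[fit_idx], seed=seed)
        pred = model.predict_standardized(X[val_idx])
        rmses.append(float(np.sqrt(np.mean((y[val_idx] - pred) ** 2))))
    return float(np.mean(rmses))


# ---------------------------------------------------------------------------
# TPE internals

def _bandwidths(values: np.ndarray, dim: Dimension) -> np.ndarray:
    """Per-component bandwidths from neighbor spacing, clamped to the span."""
    span = max(dim.hi - dim.lo, 1e-12)
    if len(values) == 1:
        return np.array([span / 2])
    order = np.argsort(values)
    sorted_v = values[order]
    gaps = np.diff(sorted_v)
    bw_sorted = np.empty_like(sorted_v)
    bw_sorted[0] = gaps[0]
    bw_sorted[-1] = gaps[-1]
    if len(values) > 2:
        bw_sorted[1:-1] = np.maximum(gaps[:-1], gaps[1:])
    bw = np.empty_like(bw_sorted)
    bw[order] = bw_sorted
    return np.clip(bw, 0.01 * span, span)


def _log_parzen(x: float, centers: np.ndarray, bw: np.ndarray, dim: Dimension) -> float:
    # Mixture of Gaussians plus a uniform floor over the span, so unseen
    # regions never get zero density.
    span = max(dim.hi - dim.lo, 1e-12)
    comp = np.exp(-0.5 * ((x - centers) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    dens = 0.95 * comp.mean() + 0.05 / span
    return float(np.log(dens))


def _tpe_propose(
    space: HyperparameterSpace,
    history: list[tuple[dict[str, Any], float]],
    rng: np.random.Generator,
) -> dict[str, Any]:
    objs = np.array([o for _, o in history])
    n_good = max(2, int(np.ceil(TPE_GAMMA * len(history))))
    order = np.argsort(objs, kind="stable")
    good = [history[i][0] for i in order[:n_good]]
    bad = [history[i][0] for i in order[n_good:]]
    if not bad:
        return space.sample(rng)

    best_cand, best_score = None, -np.inf
    good_v = {d.name: np.array([float(h[d.name]) for h in good]) for d in space.dims}
    bad_v = {d.name: np.array([float(h[d.name]) for h in bad]) for d in space.dims}
    good_bw = {d.name: _bandwidths(good_v[d.name], d) for d in space.dims}
    bad_bw = {d.name: _bandwidths(bad_v[d.name], d) for d in space.dims}

    for _ in range(TPE_N_CANDIDATES):
        cand: dict[str, Any] = {}
        score = 0.0
        for d in space.dims:
            centers, bw = good_v[d.name], good_bw[d.name]
            if rng.random() < 0.05:  # uniform exploration component
                v = d.hi - rng.random() * (d.hi - d.lo)
            else:
                j = rng.integers(len(centers))
                v = rng.normal(centers[j], bw[j])
                lo_eff = d.lo + 1e-9 * (d.hi - d.lo) if d.lo_open else d.lo
                v = float(np.clip(v, lo_eff, d.hi))
            if d.dtype == "integer":
                v = int(np.clip(round(v), np.ceil(d.lo), np.floor(d.hi)))
            cand[d.name] = v
            score += _log_parzen(float(v), centers, bw, d)
            score -= _log_parzen(float(v), bad_v[d.name], bad_bw[d.name], d)
        if score > best_score:
            best_cand, best_score = cand, score
    return best_cand


def tune(
    model_kind: str,
    space: HyperparameterSpace | None,
    X: np.ndarray,
    y: np.ndarray,
    config: TuningConfig,
    folds: list[np.ndarray] | None = None,
    objective_fn: Callable[[dict[str, Any]], float] | None = None,
) -> TuningResult:
    """Minimize the CV objective over the model's hyperparameter space.

    ``objective_fn`` overrides the default cross-validation objective (used
    by tests with analytic toy objectives)."""
    space = space if space is not None else SPACES[model_kind]
    if space.model_kind != model_kind:
        raise ValueError(f"space is for {space.model_kind}, not {model_kind}")
    if objective_fn is None:
        if folds is None:
            folds = make_positional_folds(len(X), config.K, config.seed)
        objective_fn = lambda hp: cv_objective(  # noqa: E731
            model_kind, hp, X, y, folds, seed=config.seed
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7FE1]))
    history: list[tuple[dict[str, Any], float]] = []
    for i in range(config.budget):
        if i < TPE_N_STARTUP or len(history) < 4:
            hp = space.sample(rng)
        else:
            hp = _tpe_propose(space, history, rng)
        space.validate(hp)
        history.append((hp, float(objective_fn(hp))))
    best_hp, best_obj = min(history, key=lambda t: t[1])
    return TuningResult(dict(best_hp), best_obj, history, budget_used=len(history))


def random_search(
    model_kind: str,
    space: HyperparameterSpace | None,
    config: TuningConfig,
    objective_fn: Callable[[dict[str, Any]], float],
) -> TuningResult:
    """Pure random-search baseline over the same space (used as a yardstick)."""
    space = space if space is not None else SPACES[model_kind]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7FE1]))
    history = []
    for _ in range(config.budget):
        hp = space.sample(rng)
        history.append((hp, float(objective_fn(hp))))
    best_hp, best_obj = min(history, key=lambda t: t[1])
    return TuningResult(dict(best_hp), best_obj, history, budget_used=len(history))
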