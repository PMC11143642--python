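"""Feature standardization, outlier screening, and train/test/fold plumbing.

The two dose features (GA3, ZT in mg/L) are z-scored with moments estimated
on the training subset only; the four growth responses stay in raw trait
units. Rows are split 80/20 at random per cultivar, and the training rows
are further partitioned into K = 10 cross-validation folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("culturopt")

FEATURES = ["ga3_mg_per_L", "zt_mg_per_L"]
RESPONSES = ["LN", "PR", "ES_pct", "SL_cm"]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and standard deviation (z = (x - mu) / sigma)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("standardization undefined: sigma must be > 0")

    def to_dict(self) -> dict:
        return {"mu": list(map(float, self.mu)), "sigma": list(map(float, self.sigma))}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(mu=np.asarray(d["mu"], float), sigma=np.asarray(d["sigma"], float))


def fit_standardizer(table: pd.DataFrame, indices: np.ndarray) -> StandardizationParams:
    """Estimate feature moments on the given (training) rows only."""
    idx = np.asarray(indices)
    if idx.size == 0:
        raise ValueError("cannot fit standardizer on an empty index set")
    X = table.iloc[idx][FEATURES].to_numpy(float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    if np.any(sigma == 0):
        bad = [f for f, s in zip(FEATURES, sigma) if s == 0]
        raise ValueError(f"zero variance in feature(s) {bad}: standardization undefined")
    return StandardizationParams(mu=mu, sigma=sigma)


def standardize(x: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return (np.asarray(x, float) - params.mu) / params.sigma


def destandardize(z: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return np.asarray(z, float) * params.sigma + params.mu


@dataclass
class SplitPlan:
    """Reproducible 80/20 split plus K-fold assignment over the training rows."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fold_assignment: dict[int, int] = field(repr=False)  # train row -> fold 1..K
    seed: int = 0
    K: int = 10

    def folds(self) -> list[np.ndarray]:
        """Training indices per fold, ordered fold 1..K."""
        out = []
        for k in range(1, self.K + 1):
            out.append(np.array([i for i, f in self.fold_assignment.items() if f == k]))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "fold_assignment": {str(k): v for k, v in self.fold_assignment.items()},
            "seed": self.seed,
            "K": self.K,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            train_indices=np.asarray(d["train_indices"], int),
            test_indices=np.asarray(d["test_indices"], int),
            fold_assignment={int(k): v for k, v in d["fold_assignment"].items()},
            seed=d["seed"],
            K=d["K"],
        )


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.8, seed: int = 0, K: int = 10
) -> SplitPlan:
    """Random 80/20 row split with a balanced K-fold partition of the training set."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B17]))
    n = len(table)
    perm = rng.permutation(n)
    n_train = round(fraction * n)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])

    # Balanced fold sizes (differing by at most one), randomized membership.
    fold_perm = rng.permutation(train)
    sizes = np.full(K, len(train) // K)
    sizes[: len(train) % K] += 1
    fold_assignment: dict[int, int] = {}
    pos = 0
    for k, size in enumerate(sizes, start=1):
        for i in fold_perm[pos : pos + size]:
            fold_assignment[int(i)] = k
        pos += size
    return SplitPlan(train, test, fold_assignment, seed=seed, K=K)


def pca_outlier_screen(table: pd.DataFrame, threshold: float = 3.0) -> np.ndarray:
    """Flag rows whose score on either of the first two principal components
    of the standardized response matrix exceeds ``threshold`` standard
    deviations. Rows are reported, never dropped."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a PCA screen")
    Y = table[RESPONSES].to_numpy(float)
    sd = Y.std(axis=0, ddof=0)
    if np.all(sd == 0):
        logger.warning("pca_outlier_screen: degenerate constant matrix, nothing to screen")
        return np.array([], dtype=int)
    keep = sd > 0
    Z = (Y[:, keep] - Y[:, keep].mean(axis=0)) / sd[keep]
    # PCA via SVD of the centred, scaled matrix.
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    n_pc = min(2, Vt.shape[0])
    scores = Z @ Vt[:n_pc].T
    score_sd = scores.std(axis=0, ddof=0)
    score_sd[score_sd == 0] = 1.0
    flagged = np.where(np.any(np.abs(scores / score_sd) > threshold, axis=1))[0]
    if flagged.size:
        logger.info("pca_outlier_screen: flagged %d row(s)", flagged.size)
    return flagged
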