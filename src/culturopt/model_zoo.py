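"""The five surrogate families behind one fit/predict contract.

Four standalone regressors — support vector regression with an RBF kernel
(SVR), random forest (RF), gradient-boosted trees (XGB) and elastic-net
linear regression (ENMLR) — plus the stacking ensemble (ESR) that uses XGB,
SVR and ENMLR as base regressors and an RF meta-regressor trained on their
out-of-fold predictions. Solver internals are delegated to scikit-learn and
xgboost; this module owns the hyperparameter-space contracts, the stacking
construction, and the dose -> prediction interface.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.svm import SVR as _SkSVR
from xgboost import XGBRegressor

from .preprocess import StandardizationParams, standardize
from .synthetic_data import TRAIT_BOUNDS

logger = logging.getLogger("culturopt")

MODEL_KINDS = ("XGB", "RF", "SVR", "ENMLR", "ESR")
BASE_KINDS = ("XGB", "SVR", "ENMLR")

#: Experimental dose rectangle (mg/L); surrogates are not trusted outside it.
DOSE_BOUNDS = {"ga3": (0.0, 0.5), "zt": (0.0, 0.75)}


@dataclass(frozen=True)
class Dimension:
    name: str
    lo: float
    hi: float
    dtype: str = "continuous"  # or "integer"
    lo_open: bool = False

    def contains(self, value: float) -> bool:
        if self.dtype == "integer" and float(value) != int(value):
            return False
        if self.lo_open:
            return self.lo < value <= self.hi
        return self.lo <= value <= self.hi

    def sample(self, rng: np.random.Generator) -> float:
        # hi - u*(hi-lo) with u in [0,1) covers (lo, hi] for open-low dims.
        v = self.hi - rng.random() * (self.hi - self.lo)
        if self.dtype == "integer":
            v = int(np.clip(round(v), np.ceil(self.lo), np.floor(self.hi)))
        return v


@dataclass(frozen=True)
class HyperparameterSpace:
    model_kind: str
    dims: tuple[Dimension, ...]

    def validate(self, hyperparams: dict[str, Any]) -> None:
        names = {d.name for d in self.dims}
        for key in hyperparams:
            if key not in names:
                raise ValueError(f"{self.model_kind}: unknown hyperparameter {key!r}")
        for d in self.dims:
            if d.name not in hyperparams:
                raise ValueError(f"{self.model_kind}: missing hyperparameter {d.name!r}")
            v = hyperparams[d.name]
            if not d.contains(v):
                interval = f"{'(' if d.lo_open else '['}{d.lo}, {d.hi}]"
                raise ValueError(
                    f"{self.model_kind}: hyperparameter {d.name!r}={v} outside {interval}"
                )

    def sample(self, rng: np.random.Generator) -> dict[str, Any]:
        return {d.name: d.sample(rng) for d in self.dims}


def _dims(*specs) -> tuple[Dimension, ...]:
    return tuple(Dimension(*s) for s in specs)


SPACES: dict[str, HyperparameterSpace] = {
    "XGB": HyperparameterSpace("XGB", _dims(
        ("n_estimators", 10, 1500, "integer"),
        ("learning_rate", 0.001, 0.3),
        ("gamma", 0.0, 10.0),
        ("max_depth", 1, 20, "integer"),
        ("subsample", 0.001, 1.0),
        ("colsample_bytree", 0.01, 1.0),
        ("min_child_weight", 1.0, 10.0),
        ("reg_lambda", 0.0, 5.0),
        ("reg_alpha", 0.0, 5.0),
    )),
    "RF": HyperparameterSpace("RF", _dims(
        ("n_estimators", 10, 1500, "integer"),
        ("max_features", 0.0, 1.0, "continuous", True),
        ("max_depth", 2, 50, "integer"),
        ("min_samples_split", 1, 100, "integer"),
        ("min_samples_leaf", 1, 15, "integer"),
        ("min_weight_fraction_leaf", 0.0, 0.5),
        ("max_leaf_nodes", 2, 200, "integer"),
    )),
    "ENMLR": HyperparameterSpace("ENMLR", _dims(
        ("alpha", 0.0, 5.0),
        ("l1_ratio", 0.0, 1.0),
    )),
    "SVR": HyperparameterSpace("SVR", _dims(
        ("gamma", 0.0, 10.0, "continuous", True),
        ("C", 0.0, 50.0, "continuous", True),
        ("epsilon", 0.0, 5.0, "continuous", True),
    )),
}


@dataclass
class SurrogateModel:
    """A fitted regressor mapping raw (GA3, ZT) dose pairs to one trait.

    ``fitted_state`` is the opaque underlying estimator (or, for ESR, the
    dict of base estimators plus the meta-regressor)."""

    model_kind: str
    hyperparams: dict[str, Any]
    fitted_state: Any
    standardizer: StandardizationParams | None = None
    trait: str | None = None
    cultivar: str | None = None
    seed: int = 0
    extras: dict[str, Any] = field(default_factory=dict)

    def predict_standardized(self, Z: np.ndarray) -> np.ndarray:
        """Predict from already-standardized features."""
        Z = np.atleast_2d(np.asarray(Z, float))
        if self.model_kind == "ESR":
            meta = np.column_stack(
                [self.fitted_state["bases"][k].predict_standardized(Z)
                 for k in BASE_KINDS]
            )
            return self.fitted_state["meta"].predict(meta)
        if self.model_kind == "SVR":
            # SVR targets are fitted on a standardized scale (epsilon is
            # scale-sensitive); undo that here.
            y_mu, y_sd = self.extras["y_mu"], self.extras["y_sd"]
            return self.fitted_state.predict(Z) * y_sd + y_mu
        return self.fitted_state.predict(Z)


def _build_estimator(model_kind: str, hp: dict[str, Any], seed: int):
    if model_kind == "XGB":
        return XGBRegressor(
            n_estimators=int(hp["n_estimators"]),
            learning_rate=hp["learning_rate"],
            gamma=hp["gamma"],
            max_depth=int(hp["max_depth"]),
            subsample=hp["subsample"],
            colsample_bytree=hp["colsample_bytree"],
            min_child_weight=hp["min_child_weight"],
            reg_lambda=hp["reg_lambda"],
            reg_alpha=hp["reg_alpha"],
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    if model_kind == "RF":
        return RandomForestRegressor(
            n_estimators=int(hp["n_estimators"]),
            max_features=hp["max_features"],
            max_depth=int(hp["max_depth"]),
            # scikit-learn requires an integer min_samples_split >= 2.
            min_samples_split=max(2, int(hp["min_samples_split"])),
            min_samples_leaf=int(hp["min_samples_leaf"]),
            min_weight_fraction_leaf=hp["min_weight_fraction_leaf"],
            max_leaf_nodes=int(hp["max_leaf_nodes"]),
            n_jobs=1,
            random_state=seed,
        )
    if model_kind == "ENMLR":
        if hp["alpha"] == 0.0:
            # Unpenalized limit; ElasticNet's coordinate descent is not
            # meant for alpha = 0.
            return LinearRegression()
        return ElasticNet(alpha=hp["alpha"], l1_ratio=hp["l1_ratio"], max_iter=10000)
    if model_kind == "SVR":
        return _SkSVR(kernel="rbf", gamma=hp["gamma"], C=hp["C"], epsilon=hp["epsilon"])
    raise ValueError(f"unknown model kind {model_kind!r}")


def fit(
    model_kind: str,
    hyperparams: dict[str, Any],
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    standardizer: StandardizationParams | None = None,
    trait: str | None = None,
    cultivar: str | None = None,
) -> SurrogateModel:
    """Fit one standalone surrogate on standardized features ``X``."""
    if model_kind not in SPACES:
        raise ValueError(f"unknown model kind {model_kind!r} (ESR uses fit_stacking)")
    SPACES[model_kind].validate(hyperparams)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) != len(y) or len(y) < 2:
        raise ValueError("need |X| = |y| >= 2")
    extras: dict[str, Any] = {}
    if model_kind == "SVR":
        y_mu, y_sd = float(y.mean()), float(y.std(ddof=0))
        y_sd = y_sd if y_sd > 0 else 1.0
        extras = {"y_mu": y_mu, "y_sd": y_sd}
        y_fit = (y - y_mu) / y_sd
    else:
        y_fit = y
    est = _build_estimator(model_kind, hyperparams, seed)
    est.fit(X, y_fit)
    return SurrogateModel(
        model_kind, dict(hyperparams), est,
        standardizer=standardizer, trait=trait, cultivar=cultivar,
        seed=seed, extras=extras,
    )


def predict(
    model: SurrogateModel,
    doses: np.ndarray,
    extrapolate: bool = False,
    clip: bool = True,
) -> np.ndarray:
    """Predict the trait at raw (ga3, zt) dose pairs.

    Standardizes doses with the model's own fitted parameters, then applies
    the regressor. By default predictions are clipped to the trait's valid
    range at report time (survival percentages cannot leave [0, 100]) and
    doses outside the experimental rectangle raise an error."""
    doses = np.atleast_2d(np.asarray(doses, float))
    if doses.shape[1] != 2:
        raise ValueError("doses must be (n, 2) pairs of (ga3, zt)")
    if not extrapolate:
        (g_lo, g_hi), (z_lo, z_hi) = DOSE_BOUNDS["ga3"], DOSE_BOUNDS["zt"]
        if (np.any(doses[:, 0] < g_lo) or np.any(doses[:, 0] > g_hi)
                or np.any(doses[:, 1] < z_lo) or np.any(doses[:, 1] > z_hi)):
            raise ValueError(
                "dose outside experimental bounds "
                f"GA3 {DOSE_BOUNDS['ga3']}, ZT {DOSE_BOUNDS['zt']}; "
                "pass extrapolate=True to override"
            )
    if model.standardizer is None:
        raise ValueError("model has no standardizer attached; cannot map raw doses")
    Z = standardize(doses, model.standardizer)
    pred = model.predict_standardized(Z)
    if clip and model.trait is not None:
        lo, hi = TRAIT_BOUNDS[model.trait]
        pred = np.clip(pred, lo, hi)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("non-finite surrogate prediction")
    return pred


def fit_stacking(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    base_params: dict[str, dict[str, Any]],
    meta_params: dict[str, Any] | None = None,
    seed: int = 0,
    standardizer: StandardizationParams | None = None,
    trait: str | None = None,
    cultivar: str | None = None,
    meta_n_estimators: int = 300,
) -> SurrogateModel:
    """Fit the stacking ensemble (ESR).

    Meta-features are out-of-fold predictions: for each fold, every base
    model is refitted on the remaining folds and predicts the held-out rows,
    so no base prediction comes from a model that saw that row. The RF
    meta-regressor is trained on the resulting 3-column matrix; base models
    are then refitted on all rows for test-time meta-feature generation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    missing = set(BASE_KINDS) - set(base_params)
    if missing:
        raise ValueError(f"missing base hyperparameters for {sorted(missing)}")
    all_idx = np.sort(np.concatenate(folds)) if folds else np.array([], int)
    if folds and not np.array_equal(all_idx, np.arange(len(X))):
        raise ValueError("folds must partition all training rows exactly once")

    n = len(X)
    oof = np.full((n, len(BASE_KINDS)), np.nan)
    oof_fold = np.full(n, -1, dtype=int)  # bookkeeping for the leakage guard
    for k, val_idx in enumerate(folds):
        fit_idx = np.setdiff1d(np.arange(n), val_idx)
        for j, kind in enumerate(BASE_KINDS):
            try:
                m = fit(kind, base_params[kind], X[fit_idx], y[fit_idx], seed=seed)
            except Exception as exc:  # noqa: BLE001 - re-raise naming the base
                raise RuntimeError(f"stacking aborted: base {kind} failed to fit") from exc
            oof[val_idx, j] = m.predict_standardized(X[val_idx])
        oof_fold[val_idx] = k
    if np.any(np.isnan(oof)):
        raise RuntimeError("stacking: out-of-fold matrix incomplete")

    if meta_params is not None:
        SPACES["RF"].validate(meta_params)
        meta = _build_estimator("RF", meta_params, seed)
    else:
        meta = RandomForestRegressor(n_estimators=meta_n_estimators, n_jobs=1,
                                     random_state=seed)
    meta.fit(oof, y)

    bases = {}
    for kind in BASE_KINDS:
        try:
            bases[kind] = fit(kind, base_params[kind], X, y, seed=seed)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stacking aborted: base {kind} failed to fit") from exc

    return SurrogateModel(
        "ESR",
        {"bases": {k: dict(v) for k, v in base_params.items()},
         "meta": dict(meta_params) if meta_params else {"n_estimators": meta_n_estimators}},
        {"bases": bases, "meta": meta},
        standardizer=standardizer, trait=trait, cultivar=cultivar, seed=seed,
        extras={"oof_features": oof, "oof_fold": oof_fold},
    )


def save_model(model: SurrogateModel, prefix: str | Path) -> None:
    """Persist a model as a JSON manifest plus an opaque fitted blob."""
    prefix = Path(prefix)
    manifest = {
        "model_kind": model.model_kind,
        "hyperparams": model.hyperparams,
        "trait": model.trait,
        "cultivar": model.cultivar,
        "seed": model.seed,
        "standardizer": model.standardizer.to_dict() if model.standardizer else None,
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2, default=float))
    with open(prefix.with_suffix(".pkl"), "wb") as f:
        pickle.dump(model, f)


def load_model(prefix: str | Path) -> SurrogateModel:
    with open(Path(prefix).with_suffix(".pkl"), "rb") as f:
        return pickle.load(f)
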