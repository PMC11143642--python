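"""End-to-end orchestration: generate -> preprocess -> tune -> fit ->
evaluate -> GPI-rank -> optimize, with per-run manifests.

All randomness flows from a single root seed through named substreams
(data, split, tuner, model, optimizer), so a manifest replays a run
bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import model_zoo as mz
from . import optimize as opt
from . import preprocess as pp
from . import synthetic_data as sd
from .tune import TuningConfig, tune as tune_model

logger = logging.getLogger("culturopt")


def substream_seed(root_seed: int, name: str) -> int:
    """Derived integer seed (< 2^31) for a named substream."""
    return (int(root_seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 42
    n_rep: int = 20
    cultivars: tuple[str, ...] = sd.CULTIVARS
    budget: int = 30
    K: int = 10
    fraction: float = 0.8
    models: tuple[str, ...] = mz.MODEL_KINDS
    mape_denominator: str = "predicted"
    optimizer: opt.OptimizerConfig = field(default_factory=opt.OptimizerConfig)
    outdir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        optimizer = opt.OptimizerConfig(**raw.pop("optimizer", {}))
        cfg = cls(**{k: tuple(v) if k in ("cultivars", "models") else v
                     for k, v in raw.items()}, optimizer=optimizer)
        return cfg


def _cultivar_table(table: pd.DataFrame, cultivar: str) -> pd.DataFrame:
    return table[table.cultivar == cultivar].reset_index(drop=True)


def prepare_cultivar(table: pd.DataFrame, cultivar: str, config: RunConfig) -> dict:
    """Split one cultivar's rows, fit the standardizer on train, build folds."""
    sub = _cultivar_table(table, cultivar)
    split = pp.split_train_test(
        sub, fraction=config.fraction,
        seed=substream_seed(config.seed, f"split/{cultivar}"), K=config.K,
    )
    params = pp.fit_standardizer(sub, split.train_indices)
    X_all = pp.standardize(sub[pp.FEATURES].to_numpy(float), params)
    # positional folds over the training rows, derived from the split plan
    train = split.train_indices
    pos_of = {int(r): i for i, r in enumerate(train)}
    folds = [np.array(sorted(pos_of[int(r)] for r in f)) for f in split.folds()]
    return {
        "table": sub, "split": split, "standardizer": params,
        "X_train": X_all[train], "X_test": X_all[split.test_indices],
        "folds": folds,
    }


TRAIT_COLUMNS = {"LN": "LN", "PR": "PR", "ES": "ES_pct", "SL": "SL_cm"}


def fit_trait_models(
    prep: dict, cultivar: str, trait: str, config: RunConfig,
    model_kinds: tuple[str, ...],
) -> dict[str, mz.SurrogateModel]:
    """Tune and fit the requested surrogates for one (cultivar, trait).

    Fitting ESR implies tuning its three base regressors; the RF
    meta-regressor uses fixed defaults (see docs)."""
    y_train = prep["table"].iloc[prep["split"].train_indices][
        TRAIT_COLUMNS[trait]].to_numpy(float)
    X_train, folds = prep["X_train"], prep["folds"]
    needs_tuning = set()
    for kind in model_kinds:
        needs_tuning.update(mz.BASE_KINDS if kind == "ESR" else {kind})

    tuned: dict[str, dict] = {}
    for kind in sorted(needs_tuning):
        tcfg = TuningConfig(
            budget=config.budget, K=config.K,
            seed=substream_seed(config.seed, f"tuner/{cultivar}/{trait}/{kind}"),
        )
        result = tune_model(kind, mz.SPACES[kind], X_train, y_train, tcfg, folds=folds)
        tuned[kind] = result.best_hyperparams
        logger.info("tuned %s/%s/%s: cv_rmse=%.4f", cultivar, trait, kind,
                    result.best_objective)

    models: dict[str, mz.SurrogateModel] = {}
    for kind in model_kinds:
        mseed = substream_seed(config.seed, f"model/{cultivar}/{trait}/{kind}")
        if kind == "ESR":
            models[kind] = mz.fit_stacking(
                X_train, y_train, folds,
                base_params={k: tuned[k] for k in mz.BASE_KINDS},
                seed=mseed, standardizer=prep["standardizer"],
                trait=trait, cultivar=cultivar,
            )
        else:
            models[kind] = mz.fit(
                kind, tuned[kind], X_train, y_train, seed=mseed,
                standardizer=prep["standardizer"], trait=trait, cultivar=cultivar,
            )
    return models


def evaluate_models(prep: dict, models: dict[str, mz.SurrogateModel],
                    cultivar: str, trait: str, config: RunConfig) -> list[ev.MetricReport]:
    reports = []
    col = TRAIT_COLUMNS[trait]
    for subset, idx, X in (
        ("train", prep["split"].train_indices, prep["X_train"]),
        ("test", prep["split"].test_indices, prep["X_test"]),
    ):
        y = prep["table"].iloc[idx][col].to_numpy(float)
        for kind, model in models.items():
            pred = model.predict_standardized(X)
            reports.append(ev.compute_metrics(
                y, pred, mape_denominator=config.mape_denominator,
                cultivar=cultivar, trait=trait, model_kind=kind, subset=subset,
            ))
    return reports


def optimize_cultivar(
    surrogates: dict[str, mz.SurrogateModel], config: RunConfig
) -> tuple[list[opt.ParetoSolution], opt.ParetoSolution]:
    """Run NSGA-II on one cultivar's four ESR surrogates."""
    cultivar = next(iter(surrogates.values())).cultivar or ""
    ocfg = opt.OptimizerConfig(
        **{**asdict(config.optimizer),
           "seed": substream_seed(config.seed, f"optimizer/{cultivar}")},
    )
    front = opt.run_nsga2(opt.surrogate_objectives(surrogates), ocfg)
    return front, opt.select_compromise(front)


def run_esr_optimization(cultivar: str, config: RunConfig,
                         stats: list[sd.TreatmentStats] | None = None) -> dict:
    """Generate -> split -> tune bases -> stack -> NSGA-II for one cultivar.

    This is the path behind the reported optimal-dose results; it fits only
    the ESR surrogate (and its bases) per trait."""
    stats = stats if stats is not None else sd.load_treatment_stats()
    table = sd.generate(stats, seed=substream_seed(config.seed, "data"),
                        n_rep=config.n_rep, cultivars=(cultivar,))
    prep = prepare_cultivar(table, cultivar, config)
    surrogates = {}
    for trait in sd.TRAITS:
        models = fit_trait_models(prep, cultivar, trait, config, ("ESR",))
        surrogates[trait] = models["ESR"]
    front, compromise = optimize_cultivar(surrogates, config)
    return {"table": table, "prep": prep, "surrogates": surrogates,
            "front": front, "compromise": compromise}


def run_all(config: RunConfig) -> dict:
    """Full pipeline over all requested cultivars and model kinds."""
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stats = sd.load_treatment_stats()
    table = sd.generate(stats, seed=substream_seed(config.seed, "data"),
                        n_rep=config.n_rep, cultivars=config.cultivars)
    flagged = pp.pca_outlier_screen(table)
    logger.info("run_all: PCA screen flagged %d row(s)", len(flagged))

    all_reports: list[ev.MetricReport] = []
    gpi_tables: dict[tuple[str, str], ev.GPIResult] = {}
    optima: dict[str, dict] = {}
    for cultivar in config.cultivars:
        prep = prepare_cultivar(table, cultivar, config)
        if outdir:
            prep["split"].to_json(outdir / f"split_{cultivar}.json")
        esr_surrogates = {}
        for trait in sd.TRAITS:
            models = fit_trait_models(prep, cultivar, trait, config, config.models)
            all_reports.extend(evaluate_models(prep, models, cultivar, trait, config))
            if set(config.models) == set(mz.MODEL_KINDS):
                vals = {
                    r.model_kind: r.indicator_vector()
                    for r in all_reports
                    if (r.cultivar, r.trait, r.subset) == (cultivar, trait, "test")
                }
                gpi_tables[(cultivar, trait)] = ev.compute_gpi(
                    vals, cultivar=cultivar, trait=trait, subset="test")
            if "ESR" in models:
                esr_surrogates[trait] = models["ESR"]
        if len(esr_surrogates) == len(sd.TRAITS):
            front, compromise = optimize_cultivar(esr_surrogates, config)
            optima[cultivar] = {"front": front, "compromise": compromise}
            if outdir:
                opt.front_to_frame(front).to_csv(
                    outdir / f"pareto_{cultivar}.csv", index=False)
                opt.write_optimum(compromise, outdir / f"optimum_{cultivar}.json",
                                  seed=config.seed)

    metrics_df = pd.DataFrame([vars(r) for r in all_reports])
    ranking = ev.rank_models(gpi_tables) if len(gpi_tables) == 12 else None
    manifest = {
        "seed": config.seed, "n_rep": config.n_rep,
        "cultivars": list(config.cultivars), "budget": config.budget,
        "K": config.K, "models": list(config.models),
        "optimizer": asdict(config.optimizer),
        "flagged_outliers": [int(i) for i in flagged],
        "wall_time_s": round(time.time() - t0, 2),
    }
    if outdir:
        metrics_df.to_csv(outdir / "metrics.csv", index=False)
        if gpi_tables:
            gpi_rows = [
                {"cultivar": c, "trait": t, "model": m,
                 "gpi": res.gpi[m], "rank": res.ranks[m]}
                for (c, t), res in gpi_tables.items() for m in res.models
            ]
            pd.DataFrame(gpi_rows).to_csv(outdir / "gpi.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"table": table, "metrics": metrics_df, "gpi": gpi_tables,
            "ranking": ranking, "optima": optima, "manifest": manifest}


def verify_gpi_fixture() -> dict:
    """Recompute every GPI value from the published testing-set metrics and
    diff against the published GPI table."""
    fixtures = ev.load_metric_fixtures()
    printed = ev.load_printed_gpi()
    deviations = []
    rank1 = {}
    for (cultivar, trait), grp in printed.groupby(["cultivar", "trait"]):
        res = ev.gpi_from_fixture(fixtures, cultivar, trait, subset="test")
        rank1[(cultivar, trait)] = min(res.ranks, key=res.ranks.get)
        for row in grp.itertuples():
            deviations.append({
                "cultivar": cultivar, "trait": trait, "model": row.model,
                "printed": float(row.gpi), "recomputed": res.gpi[row.model],
                "abs_dev": abs(res.gpi[row.model] - float(row.gpi)),
            })
    max_dev = max(d["abs_dev"] for d in deviations)
    return {
        "n_values": len(deviations),
        "max_abs_deviation": max_dev,
        "rank1_models": rank1,
        "all_rank1_esr": all(m == "ESR" for m in rank1.values()),
        "deviations": deviations,
    }
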