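"""Model evaluation statistics and Global Performance Indicator (GPI) ranking.

Six statistics are computed per (cultivar, trait, model, subset):

    R      Pearson correlation between observed O and predicted P
    R^2    squared correlation
    RMSE   sqrt(mean((O - P)^2)), in trait units
    RRMSE  100 * RMSE / mean(O), percent
    MAE    mean(|O - P|), in trait units
    MAPE   100 * mean(|O - P| / P), percent

MAPE divides by the *predicted* value, matching the source convention this
package reproduces; the conventional observed-denominator form is available
via ``mape_denominator="observed"``.

The GPI ranks the five models on one (cultivar, trait, subset): each
indicator is min-max scaled across the models to [0, 1], the per-indicator
median (middle order statistic) of the scaled values is subtracted, the
differences are weighted -1 for R and R^2 and +1 for the four error
indicators, and summed. Higher GPI is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_zoo import MODEL_KINDS

logger = logging.getLogger("culturopt")

#: Indicator order used throughout (matches the published metric tables).
INDICATORS = ("RRMSE", "RMSE", "MAE", "MAPE", "R2", "R")
#: GPI weights: error indicators count +1, goodness-of-fit indicators -1.
GPI_WEIGHTS = {"RRMSE": 1.0, "RMSE": 1.0, "MAE": 1.0, "MAPE": 1.0, "R2": -1.0, "R": -1.0}


@dataclass
class MetricReport:
    R: float | None
    R2: float | None
    RMSE: float
    RRMSE: float
    MAE: float
    MAPE: float | None
    n: int
    cultivar: str | None = None
    trait: str | None = None
    model_kind: str | None = None
    subset: str | None = None

    def indicator_vector(self) -> np.ndarray:
        if self.MAPE is None or self.R is None:
            raise ValueError("missing indicator; GPI needs all six")
        return np.array([self.RRMSE, self.RMSE, self.MAE, self.MAPE, self.R2, self.R])


def compute_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    mape_denominator: str = "predicted",
    **labels,
) -> MetricReport:
    """All six statistics for one observed/predicted pair of vectors."""
    O = np.asarray(observed, float)
    P = np.asarray(predicted, float)
    if O.shape != P.shape or O.ndim != 1 or len(O) < 2:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 2")

    err = O - P
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    rrmse = float(100.0 * rmse / O.mean())
    if O.std() == 0 or P.std() == 0:
        # correlation is undefined for a constant vector; the error
        # statistics are still well defined and reported
        logger.warning("zero-variance observed or predicted vector: R undefined")
        r = None
    else:
        r = float(np.corrcoef(O, P)[0, 1])

    denom = P if mape_denominator == "predicted" else O
    if np.any(denom == 0):
        logger.warning("MAPE undefined: zero %s value(s); reported as missing",
                       mape_denominator)
        mape = None
    else:
        mape = float(100.0 * np.mean(np.abs(err) / np.abs(denom)))

    return MetricReport(R=r, R2=None if r is None else r * r, RMSE=rmse,
                        RRMSE=rrmse, MAE=mae, MAPE=mape, n=len(O), **labels)


@dataclass
class GPIResult:
    models: tuple[str, ...]
    scaled_matrix: np.ndarray  # (n_models, n_indicators), entries in [0, 1]
    medians: np.ndarray
    gpi: dict[str, float]
    ranks: dict[str, int]
    ties: bool = False
    cultivar: str | None = None
    trait: str | None = None
    subset: str | None = None
    degenerate_indicators: list[str] = field(default_factory=list)


def compute_gpi(
    indicator_values: dict[str, np.ndarray],
    cultivar: str | None = None,
    trait: str | None = None,
    subset: str | None = None,
) -> GPIResult:
    """GPI across the five models from their six-indicator vectors.

    ``indicator_values`` maps model kind -> vector in :data:`INDICATORS`
    order. An indicator that is constant across the models contributes zero
    for every model (its scaled column is all-0, logged)."""
    missing = set(MODEL_KINDS) - set(indicator_values)
    if missing:
        raise ValueError(f"missing indicator vectors for model(s) {sorted(missing)}")
    models = tuple(k for k in MODEL_KINDS)
    M = np.array([np.asarray(indicator_values[k], float) for k in models])
    if M.shape != (len(models), len(INDICATORS)):
        raise ValueError(f"expected {len(INDICATORS)} indicators per model")

    lo, hi = M.min(axis=0), M.max(axis=0)
    span = hi - lo
    degenerate = [INDICATORS[j] for j in range(len(INDICATORS)) if span[j] == 0]
    if degenerate:
        logger.info("compute_gpi: degenerate indicator column(s) %s set to 0", degenerate)
    S = np.where(span > 0, (M - lo) / np.where(span > 0, span, 1.0), 0.0)
    med = np.median(S, axis=0)
    alpha = np.array([GPI_WEIGHTS[j] for j in INDICATORS])
    gpi_vals = (alpha * (med - S)).sum(axis=1)
    gpi = {m: float(g) for m, g in zip(models, gpi_vals)}

    # Rank 1 = highest GPI; ties broken lexicographically by model kind.
    order = sorted(models, key=lambda m: (-gpi[m], m))
    ties = len({round(g, 12) for g in gpi.values()}) < len(models)
    if ties:
        logger.info("compute_gpi: tied GPI values, lexicographic tie-break applied")
    ranks = {m: i + 1 for i, m in enumerate(order)}
    return GPIResult(models, S, med, gpi, ranks, ties=ties,
                     cultivar=cultivar, trait=trait, subset=subset,
                     degenerate_indicators=degenerate)


def rank_models(gpi_tables: dict[tuple[str, str], GPIResult]) -> dict:
    """Cross-combination ranking summary over the (cultivar, trait) grid."""
    from .synthetic_data import CULTIVARS, TRAITS

    for cultivar in CULTIVARS:
        for trait in TRAITS:
            if (cultivar, trait) not in gpi_tables:
                raise ValueError(f"missing GPI result for ({cultivar}, {trait})")
    ranks = {key: res.ranks for key, res in gpi_tables.items()}
    tally = {m: 0 for m in MODEL_KINDS}
    for res in gpi_tables.values():
        for m, r in res.ranks.items():
            if r == 1:
                tally[m] += 1
    return {"ranks": ranks, "rank1_tally": tally}


# ---------------------------------------------------------------------------
# Published metric fixtures

def load_metric_fixtures() -> pd.DataFrame:
    """The published per-model evaluation statistics for all three cultivars."""
    from importlib import resources

    frames = []
    for name in ("table4_atabaki", "table5_faroogh", "table6_shirineshahvar"):
        path = resources.files("culturopt").joinpath(f"data/{name}.csv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
        if df.empty:
            raise ValueError(f"fixture {name}.csv is empty")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def load_printed_gpi() -> pd.DataFrame:
    """The published GPI values and ranks (testing subset)."""
    from importlib import resources

    path = resources.files("culturopt").joinpath("data/table7_gpi.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    if df.empty:
        raise ValueError("fixture table7_gpi.csv is empty")
    return df


def gpi_from_fixture(df: pd.DataFrame, cultivar: str, trait: str,
                     subset: str = "test") -> GPIResult:
    """GPI recomputed from a published-metrics table for one combination."""
    sub = df[(df.cultivar == cultivar) & (df.trait == trait) & (df.subset == subset)]
    if len(sub) != len(MODEL_KINDS):
        raise ValueError(
            f"expected {len(MODEL_KINDS)} rows for ({cultivar}, {trait}, {subset}), "
            f"got {len(sub)}"
        )
    vals = {
        row.model: np.array([row.RRMSE_pct, row.RMSE, row.MAE, row.MAPE_pct, row.R2, row.R])
        for row in sub.itertuples()
    }
    return compute_gpi(vals, cultivar=cultivar, trait=trait, subset=subset)
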