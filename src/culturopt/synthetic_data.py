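"""Regeneration of the factorial dose-response dataset from published summary statistics.

The underlying experiment is a completely randomized factorial design:
3 pomegranate cultivars x 4 gibberellic-acid (GA3) levels x 4 zeatin (ZT)
levels, with 20 replicate explants per treatment cell and four measured
growth responses — leaf number (LN), proliferation rate (PR, shoots per
explant), explant survival (ES, %) and shoot length (SL, cm). The raw
replicates were never deposited; only the per-cell mean +/- SD is published.
This module reconstructs a dataset with the same design and first two
moments by drawing replicates from a normal law per cell, clipped to each
trait's valid range.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("culturopt")

CULTIVARS = ("Atabaki", "Faroogh", "Shirineshahvar")
GA3_LEVELS = (0.0, 0.1, 0.25, 0.5)
ZT_LEVELS = (0.0, 0.25, 0.5, 0.75)
TRAITS = ("LN", "PR", "ES", "SL")

#: Valid range per trait: ES is a percentage, the others are nonnegative.
TRAIT_BOUNDS = {
    "LN": (0.0, np.inf),
    "PR": (0.0, np.inf),
    "ES": (0.0, 100.0),
    "SL": (0.0, np.inf),
}

OBSERVATION_COLUMNS = [
    "cultivar", "ga3_mg_per_L", "zt_mg_per_L", "LN", "PR", "ES_pct", "SL_cm",
]

_TRAIT_TO_COLUMN = {"LN": "LN", "PR": "PR", "ES": "ES_pct", "SL": "SL_cm"}


class DesignError(ValueError):
    """A treatment-stats collection does not cover the full factorial design."""


@dataclass(frozen=True)
class TreatmentStats:
    """Published mean +/- SD for one (cultivar, GA3, ZT, trait) cell."""

    cultivar: str
    ga3: float
    zt: float
    trait: str
    mean: float
    sd: float
    n_rep: int = 20

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS:
            raise ValueError(f"unknown cultivar {self.cultivar!r}")
        if self.ga3 not in GA3_LEVELS:
            raise ValueError(f"GA3 level {self.ga3} not in design {GA3_LEVELS}")
        if self.zt not in ZT_LEVELS:
            raise ValueError(f"ZT level {self.zt} not in design {ZT_LEVELS}")
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.sd < 0:
            raise ValueError(
                f"negative sd {self.sd} for cell "
                f"({self.cultivar}, {self.ga3}, {self.zt}, {self.trait})"
            )
        if self.trait == "ES" and not (0.0 <= self.mean <= 100.0):
            raise ValueError(f"ES mean {self.mean} outside [0, 100]")


def default_stats_path() -> Path:
    """Path of the packaged treatment-statistics fixture."""
    return Path(str(resources.files("culturopt").joinpath("data/table3_stats.csv")))


def load_treatment_stats(fixture_path: str | Path | None = None) -> list[TreatmentStats]:
    """Load and validate the 192 per-cell summary records.

    Raises :class:`DesignError` naming the first missing (cultivar, ga3, zt,
    trait) cell if the file does not cover the complete factorial design.
    """
    path = Path(fixture_path) if fixture_path is not None else default_stats_path()
    df = pd.read_csv(path)
    required = {"cultivar", "ga3_mg_per_L", "zt_mg_per_L", "trait", "mean", "sd", "n_rep"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")

    stats = [
        TreatmentStats(
            cultivar=row.cultivar,
            ga3=float(row.ga3_mg_per_L),
            zt=float(row.zt_mg_per_L),
            trait=row.trait,
            mean=float(row.mean),
            sd=float(row.sd),
            n_rep=int(row.n_rep),
        )
        for row in df.itertuples()
    ]
    _check_complete(stats)
    return stats


def _check_complete(stats: list[TreatmentStats]) -> None:
    seen = {(s.cultivar, s.ga3, s.zt, s.trait) for s in stats}
    for cultivar in CULTIVARS:
        for ga3 in GA3_LEVELS:
            for zt in ZT_LEVELS:
                for trait in TRAITS:
                    if (cultivar, ga3, zt, trait) not in seen:
                        raise DesignError(
                            f"missing design cell ({cultivar}, GA3={ga3}, "
                            f"ZT={zt}, {trait})"
                        )
    if len(seen) != len(stats):
        raise DesignError("duplicate design cells in treatment stats")


def _cell_rng(seed: int, cultivar: str, ga3: float, zt: float, trait: str) -> np.random.Generator:
    # Per-cell substream keyed by a CRC of the cell label, so draws do not
    # depend on the order cells are processed in.
    key = f"{cultivar}|{ga3:.6g}|{zt:.6g}|{trait}".encode()
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(key)]))


def generate(
    stats: list[TreatmentStats],
    seed: int,
    n_rep: int = 20,
    cultivars: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Draw ``n_rep`` replicates per design cell around the published moments.

    Values are drawn from Normal(mean, sd) and clipped to the trait's valid
    range (clipping events are logged); a cell with sd = 0 yields the exact
    constant mean. The same (stats, seed, n_rep) always yields a bit-identical
    table.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    _check_complete(stats)
    wanted = tuple(cultivars) if cultivars is not None else CULTIVARS
    for c in wanted:
        if c not in CULTIVARS:
            raise ValueError(f"unknown cultivar {c!r}")

    by_cell: dict[tuple, TreatmentStats] = {
        (s.cultivar, s.ga3, s.zt, s.trait): s for s in stats
    }
    chunks = []
    n_clipped = 0
    for cultivar in wanted:
        for ga3 in GA3_LEVELS:
            for zt in ZT_LEVELS:
                cols: dict[str, object] = {
                    "cultivar": cultivar, "ga3_mg_per_L": ga3, "zt_mg_per_L": zt,
                }
                for trait in TRAITS:
                    s = by_cell[(cultivar, ga3, zt, trait)]
                    lo, hi = TRAIT_BOUNDS[trait]
                    if s.sd == 0.0:
                        vals = np.full(n_rep, s.mean)
                    else:
                        rng = _cell_rng(seed, cultivar, ga3, zt, trait)
                        vals = rng.normal(s.mean, s.sd, size=n_rep)
                        clipped = (vals < lo) | (vals > hi)
                        n_clipped += int(clipped.sum())
                        vals = np.clip(vals, lo, hi)
                    cols[_TRAIT_TO_COLUMN[trait]] = vals
                chunks.append(pd.DataFrame(cols))
    if n_clipped:
        logger.info("generate: clipped %d draws to trait bounds", n_clipped)
    out = pd.concat(chunks, ignore_index=True)
    return out[OBSERVATION_COLUMNS]


def write_observations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
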