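"""Image-level classification and filtering of AUV survey records.

The raw record stream is one row per scored image.  The analysis pipeline
is, in this order:

1. classify barrens on the *full* image series (the adjacency rule needs
   consecutive images),
2. drop non-reef images (> 50 % sand),
3. subset to every k-th image per transect-year (default k = 5, chosen so
   consecutive retained images no longer overlap),
4. join terrain covariates and standardise, producing the model's y and X.

An image is a barren when more than 50 % of it is bare rock AND urchins
are seen either in the image itself or in the immediately preceding or
succeeding image of the same transect-year, provided that neighbour is
also more than 50 % bare rock.  Both 50 % cut-offs are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .terrain import (
    BathymetryGrid,
    CovariateStandardization,
    logit_rugosity,
    sample_raster_at_points,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RECORD_COLUMNS",
    "AnalysisTable",
    "classify_barrens",
    "filter_reef",
    "subset_every_kth",
    "build_analysis_table",
    "write_analysis_table",
]

#: CSV schema for image records (barren_true only present in simulations).
RECORD_COLUMNS = [
    "image_id", "site_id", "ntr", "transect_id", "seq_index",
    "x_m", "y_m", "year", "depth_m", "pct_bare_rock", "pct_sand",
    "urchin_present",
]


@dataclass
class AnalysisTable:
    """Filtered records joined to standardised covariates.

    ``df`` columns: barren (0/1), ntr (0/1), year, year_coded,
    depth_std, depth_sq_std, rugosity_logit_std, x_m, y_m, site_id,
    transect_id, seq_index, depth_m, rugosity.
    """

    df: pd.DataFrame
    standardizations: dict[str, CovariateStandardization]
    first_year: int
    n_dropped_no_rugosity: int = 0
    meta: dict = field(default_factory=dict)


def _check_series(records: pd.DataFrame) -> None:
    dup = records.duplicated(subset=["transect_id", "year", "seq_index"])
    if dup.any():
        bad = records.loc[dup, ["transect_id", "year", "seq_index"]].iloc[0]
        raise ValueError(
            f"duplicated seq_index {bad['seq_index']} in transect "
            f"{bad['transect_id']}, year {bad['year']}"
        )


def classify_barrens(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the barren rule over each transect-year image series.

    barren = pct_bare_rock > 50 AND (urchin present here, or in the
    previous/next image of the same transect-year when that image is also
    > 50 % bare rock).  Adjacency never crosses transects or years, and
    operates on the full (pre-subsetting) series.  Idempotent.
    """
    _check_series(records)
    df = records.sort_values(["transect_id", "year", "seq_index"]).copy()
    rock = df["pct_bare_rock"].to_numpy(dtype=float) > 50.0
    urch = df["urchin_present"].to_numpy(dtype=bool)
    grp = df.groupby(["transect_id", "year"], sort=False)

    rock_s = pd.Series(rock, index=df.index)
    urch_s = pd.Series(urch, index=df.index)
    # a neighbour supports the rule when it is bare rock (>50%) with urchins
    support = rock_s & urch_s
    seq = df["seq_index"].to_numpy()
    prev_adjacent = pd.Series(
        np.concatenate([[False], seq[1:] == seq[:-1] + 1]), index=df.index
    )
    same_prev = grp.cumcount() > 0
    prev_support = support.groupby(
        [df["transect_id"], df["year"]], sort=False
    ).shift(1, fill_value=False)
    next_support = support.groupby(
        [df["transect_id"], df["year"]], sort=False
    ).shift(-1, fill_value=False)
    next_adjacent = pd.Series(
        np.concatenate([seq[1:] == seq[:-1] + 1, [False]]), index=df.index
    )
    same_next = grp.cumcount(ascending=False) > 0
    neighbour = (prev_support & same_prev & prev_adjacent) | (
        next_support & same_next & next_adjacent
    )
    df["barren"] = (rock_s & (urch_s | neighbour)).astype(bool)
    return df


def filter_reef(records: pd.DataFrame) -> pd.DataFrame:
    """Drop non-reef images (pct_sand strictly greater than 50)."""
    sandy = records["pct_sand"].to_numpy(dtype=float) > 50.0
    n = int(sandy.sum())
    if n:
        logger.info("filter_reef: removed %d of %d sandy images", n, len(records))
    out = records.loc[~sandy].copy()
    if out.empty:
        logger.warning("filter_reef: no reef images remain")
    return out


def subset_every_kth(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Keep positions 0, k, 2k, ... within each transect-year series.

    The stride restarts at the first image of every transect-year; the
    position is the image's rank in the current (already filtered)
    ordering by seq_index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return records.copy()
    df = records.sort_values(["transect_id", "year", "seq_index"])
    pos = df.groupby(["transect_id", "year"], sort=False).cumcount()
    return df.loc[(pos % k == 0).to_numpy()].copy()


def build_analysis_table(
    records: pd.DataFrame,
    rugosity_raster: BathymetryGrid,
    first_year: int | None = None,
    logit_epsilon: float = 1e-6,
) -> AnalysisTable:
    """Join standardised covariates to classified, filtered, subset records.

    Depth-squared is computed from *raw* depth and then standardised as its
    own column; rugosity is logit-transformed before standardisation.  Year
    is coded as integer years since the first survey year.  Records whose
    position has no underlying rugosity (nodata cell) are dropped and
    counted, mirroring the exclusion of survey area without multibeam
    mapping.
    """
    if "barren" not in records.columns:
        raise ValueError("records must be classified first (missing 'barren')")
    pts = records[["x_m", "y_m"]].to_numpy(dtype=float)
    rug, missing = sample_raster_at_points(rugosity_raster, pts)
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info(
            "build_analysis_table: dropped %d records without rugosity", n_dropped
        )
    df = records.loc[~missing].copy()
    rug = rug[~missing]
    if df.empty:
        raise ValueError("no records remain after the rugosity join")
    if first_year is None:
        first_year = int(df["year"].min())

    stz: dict[str, CovariateStandardization] = {}
    depth = df["depth_m"].to_numpy(dtype=float)
    depth_std, stz["depth"] = standardize(depth)
    depth_sq_std, stz["depth_sq"] = standardize(depth**2)
    rug_logit = logit_rugosity(rug, epsilon=logit_epsilon)
    rug_std, stz["rugosity_logit"] = standardize(rug_logit)

    out = pd.DataFrame(
        {
            "barren": df["barren"].astype(int).to_numpy(),
            "ntr": df["ntr"].astype(int).to_numpy(),
            "year": df["year"].astype(int).to_numpy(),
            "year_coded": df["year"].astype(int).to_numpy() - first_year,
            "depth_std": depth_std,
            "depth_sq_std": depth_sq_std,
            "rugosity_logit_std": rug_std,
            "x_m": df["x_m"].to_numpy(dtype=float),
            "y_m": df["y_m"].to_numpy(dtype=float),
            "site_id": df["site_id"].to_numpy(),
            "transect_id": df["transect_id"].to_numpy(),
            "seq_index": df["seq_index"].to_numpy(),
            "depth_m": depth,
            "rugosity": rug,
        }
    )
    if out.isna().any().any():
        raise ValueError("analysis table contains missing values")
    return AnalysisTable(
        df=out.reset_index(drop=True),
        standardizations=stz,
        first_year=first_year,
        n_dropped_no_rugosity=n_dropped,
    )


def write_analysis_table(table: AnalysisTable, path, sidecar_path=None) -> None:
    """Write the analysis table as CSV plus a key:value standardisation sidecar."""
    table.df.to_csv(path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write(f"first_year: {table.first_year}\n")
            fh.write(f"n_dropped_no_rugosity: {table.n_dropped_no_rugosity}\n")
            for name, s in table.standardizations.items():
                fh.write(f"{name}_mean: {s.mean!r}\n")
                fh.write(f"{name}_sd: {s.sd!r}\n")
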