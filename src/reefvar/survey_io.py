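"""Reading, validation and description of transect survey tables.

The canonical record format is one row per transect with the three
hard-substrate cover proportions already aggregated:

    reef, site, year, transect, coral, algae, other [, sand_seagrass]

as comma- or tab-separated text with a header row.  A taxon-level table
(one row per taxon per transect: reef, site, year, transect, taxon,
cover) can be ingested through a taxon -> category map; hydrozoan
*Millepora* belongs with hard coral, and sand/seagrass map to the
excluded category.  On reading, covers are closed over hard substrate
(zeros replaced multiplicatively) and sites visited only once are
dropped with a warning, since a single visit carries no information
about dynamics.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import DEFAULT_ZERO_FLOOR, close_composition, ilr_forward

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_CATEGORY_MAP",
    "read_survey",
    "write_survey",
    "validate_records",
    "survey_summary",
    "records_to_ilr",
]

CANONICAL_COLUMNS = ["reef", "site", "year", "transect", "coral", "algae", "other"]

#: Taxon-group -> category mapping for taxon-level input.  Keys are
#: lower-cased taxon labels; values are canonical categories or
#: "excluded" (soft substrate, dropped before closure).
DEFAULT_CATEGORY_MAP = {
    "hard coral": "coral",
    "scleractinia": "coral",
    "millepora": "coral",
    "macroalgae": "algae",
    "algal turf": "other",
    "coralline algae": "other",
    "calcareous algae": "other",
    "soft coral": "other",
    "sponge": "other",
    "other": "other",
    "sand": "excluded",
    "seagrass": "excluded",
}


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def _aggregate_taxa(df: pd.DataFrame, category_map: dict) -> pd.DataFrame:
    cmap = {str(k).lower(): v for k, v in category_map.items()}
    cat = df["taxon"].astype(str).str.lower().map(cmap)
    unknown = df.loc[cat.isna(), "taxon"].unique()
    if len(unknown):
        raise ValueError(f"taxa with no category mapping: {sorted(map(str, unknown))}")
    df = df.assign(category=cat)
    keep = df[df["category"] != "excluded"]
    wide = (
        keep.pivot_table(
            index=["reef", "site", "year", "transect"],
            columns="category",
            values="cover",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=["coral", "algae", "other"], fill_value=0.0)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def validate_records(df: pd.DataFrame, closed: bool = False) -> pd.DataFrame:
    """Check structure, ranges and uniqueness; return a clean copy.

    ``closed=True`` additionally requires coral+algae+other = 1.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    for c in ("reef", "site", "transect"):
        df[c] = df[c].astype(str)
    covers = df[["coral", "algae", "other"]].to_numpy(dtype=float)
    bad = ~np.isfinite(covers).all(axis=1) | (covers < 0).any(axis=1) | (covers > 1).any(axis=1)
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ValueError(f"cover proportions outside [0, 1] in rows {rows}")
    totals = covers.sum(axis=1)
    too_big = totals > 1.0 + 1e-9
    if too_big.any():
        rows = df.index[too_big].tolist()[:10]
        raise ValueError(f"cover proportions sum above 1 in rows {rows}")
    if closed and np.any(np.abs(totals - 1.0) > 1e-9):
        raise ValueError("closed records must have coral+algae+other = 1")
    dup = df.duplicated(subset=["site", "year", "transect"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValueError(f"duplicate (site, year, transect) keys in rows {rows}")
    return df


def read_survey(
    path,
    category_map: dict | None = None,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
    drop_single_visit: bool = True,
) -> pd.DataFrame:
    """Read a survey table and return closed, validated records.

    The result has the canonical columns with compositions closed over
    hard substrate (each row sums to 1) plus ``raw_total``, the
    pre-closure hard-substrate fraction of the transect line.
    """
    df = _read_table(path)
    if "taxon" in df.columns:
        df = _aggregate_taxa(df, category_map or DEFAULT_CATEGORY_MAP)
    df = validate_records(df)
    covers = df[["coral", "algae", "other"]].to_numpy(dtype=float)
    closed = np.empty_like(covers)
    for i, row in enumerate(covers):
        try:
            closed[i] = close_composition(*row, zero_floor=zero_floor).as_array()
        except ValueError as err:
            raise ValueError(f"row {df.index[i]}: {err}") from err
    out = df[["reef", "site", "year", "transect"]].copy()
    out["coral"], out["algae"], out["other"] = closed.T
    out["raw_total"] = covers.sum(axis=1)
    if drop_single_visit:
        visits = out.groupby("site")["year"].nunique()
        single = visits[visits < 2].index
        if len(single):
            warnings.warn(
                f"dropping {len(single)} site(s) visited only once: {sorted(single)}",
                stacklevel=2,
            )
            out = out[~out["site"].isin(single)]
    return out.reset_index(drop=True)


def write_survey(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write records as delimited text (lossless read round-trip)."""
    cols = [c for c in CANONICAL_COLUMNS + ["raw_total"] if c in df.columns]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, sep=sep, index=False)


def records_to_ilr(df: pd.DataFrame) -> pd.DataFrame:
    """Append ilr coordinates (y1, y2) to closed records."""
    y = ilr_forward(df[["coral", "algae", "other"]].to_numpy(dtype=float))
    out = df.copy()
    out["y1"], out["y2"] = y[..., 0], y[..., 1]
    return out


def survey_summary(df: pd.DataFrame) -> dict:
    """Descriptive statistics of a survey table.

    Counts of reefs / sites / site-visits / transects, the distribution
    of transects per site-visit, and per reef-site arithmetic mean coral
    cover as a percentage (matching how reef tables are usually
    reported, one decimal place).
    """
    if len(df) == 0:
        raise ValueError("empty survey table")
    # fixed row order makes the float reductions order-invariant
    df = df.sort_values(["reef", "site", "year", "transect"], kind="stable")
    per_visit = df.groupby(["site", "year"], sort=False).size()
    mean_cover = (
        df.groupby(["reef", "site"], sort=False)["coral"]
        .mean()
        .mul(100.0)
        .round(1)
        .to_dict()
    )
    return {
        "n_reefs": int(df["reef"].nunique()),
        "n_sites": int(df["site"].nunique()),
        "n_site_visits": int(len(per_visit)),
        "n_transects": int(len(df)),
        "transects_per_site_year": {
            "min": int(per_visit.min()),
            "median": float(per_visit.median()),
            "max": int(per_visit.max()),
        },
        "mean_coral_cover_per_reef_site": mean_cover,
    }
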