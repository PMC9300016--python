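"""Regional (FAO-area style) aggregation, ranks, outlier rule and correlation.

Both services are averaged (area-weighted) within each region of a gridded
region mask; regions are ranked (1 = highest, ties share the minimum rank
of the tied block), fishing intensity is screened with a mean + k*SD rule
(sample SD, k = 2 by default), and the export-fishing relationship across
regions is a Pearson correlation computed after excluding the flagged
regions, with a two-sided t-test p-value (df = n - 2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import CellAreas, GeoGrid, GriddedField, GridError

TABLE1_COLUMNS = [
    "area", "name", "poc_export", "export_rank",
    "fishing_intensity", "fishing_rank", "catch_pct",
    "main_gear", "main_groups",
]


class RegionError(ValueError):
    """Raised for malformed region masks or degenerate regional samples."""


@dataclass
class RegionMask:
    """Integer region label per grid cell; 0 means 'no region'."""

    grid: GeoGrid
    region_id: np.ndarray
    codes: dict[int, str]

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.shape != self.grid.shape:
            raise GridError("region_id shape does not match grid")
        present = set(np.unique(self.region_id)) - {0}
        missing = present - set(self.codes)
        if missing:
            raise RegionError(f"region ids without a code entry: {sorted(missing)}")


def region_means(field: GriddedField, mask: RegionMask,
                 areas: CellAreas) -> pd.Series:
    """Area-weighted mean of a field within each region.

    Regions with no valid cells are omitted from the result.
    """
    if mask.grid != field.grid:
        raise GridError("region mask and field must share one grid")
    if not mask.codes:
        raise RegionError("empty region set")
    out = {}
    for rid in sorted(mask.codes):
        sel = (mask.region_id == rid) & field.valid
        if not sel.any():
            continue
        w = areas.area[sel]
        out[rid] = float(np.sum(field.values[sel] * w) / np.sum(w))
    return pd.Series(out, name=field.name or "mean")


def rank_regions(values: pd.Series) -> pd.Series:
    """Descending ranks, 1 = highest; ties share the minimum rank."""
    if len(values) == 0:
        raise RegionError("cannot rank an empty region set")
    ranks = stats.rankdata(-np.asarray(values, dtype=float), method="min")
    return pd.Series(ranks.astype(int), index=values.index, name="rank")


def flag_outliers(values: pd.Series, k: float = 2.0) -> tuple[pd.Series, float, float]:
    """Flag regions exceeding mean + k * sample SD.

    Returns (flags, mean, sd) with the sample (n-1) standard deviation;
    rounding happens only at presentation, never here.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise RegionError("outlier screening needs at least 3 regions")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    flags = pd.Series(x > mean + k * sd, index=values.index, name="outlier")
    return flags, mean, sd


def corr_excluding(x: pd.Series, y: pd.Series,
                   excluded: set | frozenset | list | tuple = ()) -> tuple[float, float]:
    """Pearson r between two regional series after dropping excluded regions.

    p is the two-sided t-test with df = n - 2.
    """
    keep = [i for i in x.index if i not in set(excluded) and i in y.index]
    if len(keep) < 3:
        raise RegionError("correlation needs at least 3 retained regions")
    xv = np.asarray(x.loc[keep], dtype=float)
    yv = np.asarray(y.loc[keep], dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        raise RegionError("zero variance in a retained regional series")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


@dataclass
class RegionSummary:
    """Per-region table plus the across-region scalars."""

    table: pd.DataFrame          # index: region code; mean/rank/outlier columns
    mean_fishing: float          # across-region mean of fishing intensity
    sd_fishing: float            # across-region sample SD
    excluded: list[int]          # regions dropped from the correlation
    r: float
    p: float


def summarize_regions(export: GriddedField, fishing: GriddedField,
                      mask: RegionMask, areas: CellAreas,
                      k: float = 2.0) -> RegionSummary:
    """Full regional analysis from gridded fields."""
    me = region_means(export, mask, areas)
    mf = region_means(fishing, mask, areas)
    common = me.index.intersection(mf.index)
    return summarize_region_table(me.loc[common], mf.loc[common],
                                  names={c: mask.codes[c] for c in common}, k=k)


def summarize_region_table(mean_export: pd.Series, mean_fishing: pd.Series,
                           names: dict | None = None,
                           k: float = 2.0) -> RegionSummary:
    """Regional analysis from pre-aggregated per-region means.

    This is the desk-reproducible path: ranks, the mean + k*SD screen on
    fishing intensity, and the Pearson correlation excluding the flagged
    regions.
    """
    flags, mu, sd = flag_outliers(mean_fishing, k=k)
    excluded = [int(i) for i in flags.index[flags]]
    r, p = corr_excluding(mean_export, mean_fishing, excluded)
    table = pd.DataFrame({
        "name": pd.Series(names if names else {}, dtype=object),
        "mean_export": mean_export,
        "export_rank": rank_regions(mean_export),
        "mean_fishing": mean_fishing,
        "fishing_rank": rank_regions(mean_fishing),
        "outlier": flags,
    })
    table.index.name = "area"
    return RegionSummary(table=table, mean_fishing=mu, sd_fishing=sd,
                         excluded=excluded, r=r, p=p)


def table_report(summary: RegionSummary,
                 catch_profiles: dict | None = None) -> pd.DataFrame:
    """Assemble the per-region report, one row per region sorted by code.

    Columns mirror the regional summary table: code, name, mean export
    (2 dp), export rank, mean fishing (2 dp), fishing rank, % of global
    catch (integer) and the dominant gear / group strings when catch
    profiles are supplied. Rounding is presentation-only.
    """
    t = summary.table.sort_index()
    rows = []
    for code, row in t.iterrows():
        prof = (catch_profiles or {}).get(code)
        rows.append({
            "area": code,
            "name": row.get("name", ""),
            "poc_export": round(float(row["mean_export"]), 2),
            "export_rank": int(row["export_rank"]),
            "fishing_intensity": round(float(row["mean_fishing"]), 2),
            "fishing_rank": int(row["fishing_rank"]),
            "catch_pct": int(round(prof.global_share)) if prof else pd.NA,
            "main_gear": prof.format_gear() if prof else "",
            "main_groups": prof.format_groups() if prof else "",
        })
    return pd.DataFrame(rows, columns=TABLE1_COLUMNS)


def load_regional_fixture() -> pd.DataFrame:
    """The packaged 19-region reference table of per-area annual means.

    Columns: area code, name, mean POC export (mg C m-2 day-1) with its
    published rank, mean fishing intensity (h km-2) with its rank, % of
    global catch, and the dominant gear/group strings.
    """
    ref = importlib.resources.files("carbonfish.data") / "fao_regional_table.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
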