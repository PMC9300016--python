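"""Catch-composition summaries: per-category shares and the >=50% dominance rule.

Catch records are tabular rows (region, gear, group, tonnes). For each
region the share of every gear or species-group category is computed from
exact tonnage fractions; the 'dominant' categories are the shortest
descending-share prefix whose cumulative share reaches the threshold
(default 50% of the regional catch). Ties between equal shares are broken
by category code so the selection is deterministic. Percentages are rounded
to integers only in the report layer — selection always uses exact
fractions, which avoids artifacts right at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: declared code vocabularies (FAO capture-production style)
GEAR_CODES = ("T", "PS", "D", "SG", "LL", "UG")
GROUP_CODES = ("GF", "SP", "LP", "DF", "UF", "PC", "BC", "UC", "UM", "B", "S")

CATCH_COLUMNS = ["region", "gear", "group", "tonnes"]


class CatchError(ValueError):
    """Raised for empty or zero-total catch queries."""


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CATCH_COLUMNS if c not in records.columns]
    if missing:
        raise CatchError(f"catch records missing columns: {missing}")
    if (records["tonnes"] < 0).any():
        raise CatchError("negative tonnage in catch records")
    return records


def shares(records: pd.DataFrame, region, by: str = "gear") -> pd.Series:
    """Percentage of a region's catch per category, descending.

    ``by`` selects the categorization column ('gear' or 'group'). Equal
    shares are ordered by category code so the output is deterministic.
    """
    records = _check_records(records)
    if by not in ("gear", "group"):
        raise CatchError(f"by must be 'gear' or 'group', got {by!r}")
    sub = records[records["region"] == region]
    if sub.empty:
        raise CatchError(f"region {region!r} absent from catch records")
    total = sub["tonnes"].sum()
    if total <= 0:
        raise CatchError(f"region {region!r} has zero total catch")
    pct = (sub.groupby(by)["tonnes"].sum() / total * 100.0)
    pct = pct[pct > 0]
    # sort by share descending, then code ascending (stable tie-break)
    pct = pct.sort_index().sort_values(ascending=False, kind="stable")
    pct.name = "percent"
    return pct


def dominant(share_series: pd.Series, threshold: float = 0.50) -> pd.Series:
    """Shortest descending-order prefix cumulatively reaching the threshold.

    ``share_series`` must be sorted descending (the output of :func:`shares`);
    ``threshold`` is a fraction of the total (0.50 = half the catch).
    """
    if len(share_series) == 0:
        raise CatchError("dominant() of an empty share list")
    vals = share_series.to_numpy(dtype=float)
    if (vals[:-1] < vals[1:]).any():
        raise CatchError("shares must be sorted in descending order")
    cum = vals.cumsum() / 100.0
    n = int((cum < threshold).sum()) + 1
    n = min(n, len(share_series))
    return share_series.iloc[:n]


def global_catch_share(records: pd.DataFrame) -> pd.Series:
    """Each region's percentage of the world catch."""
    records = _check_records(records)
    if records.empty:
        raise CatchError("no catch records")
    world = records["tonnes"].sum()
    if world <= 0:
        raise CatchError("zero world catch total")
    out = records.groupby("region")["tonnes"].sum() / world * 100.0
    out.name = "global_share"
    return out


@dataclass
class CatchProfile:
    """A region's dominance report: global share plus dominant categories."""

    region: object
    global_share: float
    dominant_gear: list[tuple[str, float]]
    dominant_groups: list[tuple[str, float]]

    @staticmethod
    def _fmt(items: list[tuple[str, float]]) -> str:
        return ", ".join(f"{code} ({round(pct):d})" for code, pct in items)

    def format_gear(self) -> str:
        return self._fmt(self.dominant_gear)

    def format_groups(self) -> str:
        return self._fmt(self.dominant_groups)


def catch_profiles(records: pd.DataFrame,
                   threshold: float = 0.50) -> dict:
    """Dominance profile for every region present in the records."""
    records = _check_records(records)
    world_shares = global_catch_share(records)
    profiles = {}
    for region in world_shares.index:
        gear = dominant(shares(records, region, by="gear"), threshold)
        group = dominant(shares(records, region, by="group"), threshold)
        profiles[region] = CatchProfile(
            region=region,
            global_share=float(world_shares.loc[region]),
            dominant_gear=list(gear.items()),
            dominant_groups=list(group.items()),
        )
    return profiles
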