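"""Dual upper-quartile overlap between carbon export and fishing intensity.

A cell belongs to the overlap zone when both the export field E and the
fishing field F strictly exceed their own 75th-percentile threshold,
computed independently over a single analysis domain (the cells where E is
valid; fishing zeros are observations, not gaps). The zone is then
summarized by three area-weighted fractions: the share of ocean area it
covers and the shares of total carbon export and total fishing effort
concentrated inside it.

Thresholds are computed unweighted over cells by default (each valid cell
is one observation) while the fractions are always area-weighted; pass
``area_weighted_thresholds=True`` to weight the threshold quantiles by
cell area instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .export import ExportEnsemble
from .grid import CellAreas, GriddedField, GridError


class OverlapError(ValueError):
    """Raised for empty or incompatible overlap inputs."""


def quantile_threshold(values: np.ndarray, q: float = 0.75,
                       weights: np.ndarray | None = None) -> float:
    """Quantile of a sample, linear interpolation at position 1 + (n-1)q.

    With ``weights`` the quantile is taken on the weighted empirical
    distribution (interpolated cumulative weight).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise OverlapError("quantile of an empty sample")
    if not 0 < q < 1:
        raise OverlapError(f"quantile level must be in (0, 1), got {q}")
    if weights is None:
        return float(np.quantile(values, q))
    weights = np.asarray(weights, dtype=float).ravel()
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w  # midpoint convention
    return float(np.interp(q * w.sum(), cw, v))


@dataclass
class OverlapResult:
    """Overlap mask with its thresholds and summary fractions."""

    q: float
    q_export: float
    q_fishing: float
    mask: np.ndarray
    area_fraction: float = np.nan
    export_fraction: float = np.nan
    effort_fraction: float = np.nan
    #: per-algorithm {name: (area_fraction, export_fraction, effort_fraction)}
    member_fractions: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def member_ranges(self) -> dict[str, tuple[float, float]]:
        """min-max envelope of the per-member fractions."""
        if not self.member_fractions:
            return {}
        arr = np.array(list(self.member_fractions.values()))
        keys = ("area_fraction", "export_fraction", "effort_fraction")
        return {k: (float(arr[:, i].min()), float(arr[:, i].max()))
                for i, k in enumerate(keys)}


def overlap_mask(E: GriddedField, F: GriddedField, q: float = 0.75,
                 areas: CellAreas | None = None,
                 area_weighted_thresholds: bool = False) -> OverlapResult:
    """Boolean dual-quartile mask with its two thresholds.

    The analysis domain is the set of cells valid in E; F must be observed
    (valid) on all of it. Strict inequality at the thresholds keeps ties out
    of the mask, which makes the zone deterministic and conservative.
    """
    if E.grid != F.grid:
        raise GridError("export and fishing fields must share one grid")
    domain = E.valid
    if not domain.any():
        raise OverlapError("empty analysis domain (no valid export cells)")
    if not F.valid[domain].all():
        raise OverlapError(
            f"{int((~F.valid & domain).sum())} domain cells lack fishing data; "
            "coerce unobserved fishing to zero before the overlap analysis"
        )
    weights = None
    if area_weighted_thresholds:
        if areas is None:
            raise OverlapError("area_weighted_thresholds requires cell areas")
        weights = areas.area[domain]
    q_export = quantile_threshold(E.values[domain], q, weights)
    q_fishing = quantile_threshold(F.values[domain], q, weights)
    mask = domain & (E.values > q_export) & (F.values > q_fishing)
    return OverlapResult(q=q, q_export=q_export, q_fishing=q_fishing, mask=mask)


def overlap_fractions(result: OverlapResult, E: GriddedField, F: GriddedField,
                      areas: CellAreas) -> tuple[float, float, float]:
    """Area, export and effort fractions of the overlap zone.

    area_fraction   = sum_mask(a) / sum_domain(a)
    export_fraction = sum_mask(E a) / sum_domain(E a)
    effort_fraction = sum_mask(F a) / sum_domain(F a)   (F a has units hours)
    """
    domain = E.valid
    a = areas.area
    denom_a = a[domain].sum()
    denom_e = (E.values * a)[domain].sum()
    denom_f = (F.values * a)[domain].sum()
    if denom_a == 0 or denom_e == 0 or denom_f == 0:
        raise OverlapError("zero domain total; fractions undefined")
    m = result.mask
    fracs = (
        float(a[m].sum() / denom_a),
        float((E.values * a)[m].sum() / denom_e),
        float((F.values * a)[m].sum() / denom_f),
    )
    result.area_fraction, result.export_fraction, result.effort_fraction = fracs
    return fracs


def compute_overlap(E: GriddedField, F: GriddedField, areas: CellAreas,
                    q: float = 0.75,
                    area_weighted_thresholds: bool = False) -> OverlapResult:
    """Convenience: mask + fractions in one call."""
    result = overlap_mask(E, F, q, areas, area_weighted_thresholds)
    overlap_fractions(result, E, F, areas)
    return result


def sensitivity(ensemble: ExportEnsemble, F: GriddedField, areas: CellAreas,
                q: float = 0.75,
                area_weighted_thresholds: bool = False) -> OverlapResult:
    """Overlap of the ensemble-mean export, with per-member fraction ranges.

    Recomputes the whole mask-and-fractions analysis once per export
    algorithm; the spread of the per-member fractions is the sensitivity of
    the overlap statistics to the choice of export parameterization.
    """
    result = compute_overlap(ensemble.mean_export, F, areas, q,
                             area_weighted_thresholds)
    for name, member in ensemble.members.items():
        member_res = compute_overlap(member, F, areas, q, area_weighted_thresholds)
        result.member_fractions[name] = (
            member_res.area_fraction,
            member_res.export_fraction,
            member_res.effort_fraction,
        )
    return result
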