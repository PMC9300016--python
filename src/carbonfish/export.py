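"""Empirical POC-export algorithms and the export ensemble.

Export out of the upper ocean is estimated as e-ratio * NPP, where the
e-ratio (export ratio) is an empirical function of sea-surface temperature,
net primary production and (for one algorithm) euphotic depth. Three
literature parameterizations ship in the registry:

``henson``   0.23 * exp(-0.08 * SST)
``laws``     0.04756 * (0.78 - 0.43 * SST / 30) * NPP**0.307
``dunne``    clip(-0.0101 * SST + 0.0582 * ln(NPP / Zeu) + 0.419, 0.04, 0.72)

plus ``model``, a pass-through for an externally supplied export product.
All ratios are clipped to [0, 1]; the registry is data, not logic, so users
may register alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grid import CellAreas, GeoGrid, GriddedField, GridError, UNITS_EXPORT, global_integral

DUNNE_FLOOR = 0.04
DUNNE_CEIL = 0.72


class AlgorithmError(ValueError):
    """Raised when an export algorithm is missing a required driver."""


def _henson_ratio(sst: np.ndarray, npp: np.ndarray, zeu: np.ndarray | None) -> np.ndarray:
    return 0.23 * np.exp(-0.08 * sst)


def _laws_ratio(sst: np.ndarray, npp: np.ndarray, zeu: np.ndarray | None) -> np.ndarray:
    # the polynomial crosses zero near SST ~ 54 degC; the [0,1] clip below guards it
    return 0.04756 * (0.78 - 0.43 * sst / 30.0) * np.power(npp, 0.307)


def _dunne_ratio(sst: np.ndarray, npp: np.ndarray, zeu: np.ndarray | None) -> np.ndarray:
    if zeu is None:
        raise AlgorithmError("dunne algorithm requires euphotic depth (zeu)")
    # NPP = 0 makes the log undefined; pin the ratio at the floor (export is
    # 0 anyway since the member field is ratio * NPP)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.log(np.divide(npp, zeu, out=np.ones_like(npp),
                                   where=(npp > 0) & (zeu > 0)))
    raw = -0.0101 * sst + 0.0582 * logterm + 0.419
    raw = np.where(npp > 0, raw, DUNNE_FLOOR)
    return np.clip(raw, DUNNE_FLOOR, DUNNE_CEIL)


#: name -> ratio(sst, npp, zeu); extend with register_algorithm()
RATIO_REGISTRY: dict[str, Callable[..., np.ndarray]] = {
    "henson": _henson_ratio,
    "laws": _laws_ratio,
    "dunne": _dunne_ratio,
}

DEFAULT_MEMBERS = ("henson", "laws", "dunne", "model")


def register_algorithm(name: str, func: Callable[..., np.ndarray]) -> None:
    """Add an e-ratio parameterization ``func(sst, npp, zeu) -> ratio``."""
    RATIO_REGISTRY[name] = func


def e_ratio(algorithm: str, sst, npp, zeu=None) -> np.ndarray:
    """Evaluate one registered e-ratio parameterization, clipped to [0, 1]."""
    try:
        func = RATIO_REGISTRY[algorithm]
    except KeyError:
        raise AlgorithmError(
            f"unknown algorithm '{algorithm}'; registered: {sorted(RATIO_REGISTRY)}"
        ) from None
    sst = np.asarray(sst, dtype=float)
    npp = np.asarray(npp, dtype=float)
    zeu = None if zeu is None else np.asarray(zeu, dtype=float)
    return np.clip(func(sst, npp, zeu), 0.0, 1.0)


@dataclass
class ExportInputs:
    """Driver fields for the export algorithms, all on one grid."""

    sst: GriddedField
    npp: GriddedField
    zeu: GriddedField | None = None
    model_export: GriddedField | None = None

    def __post_init__(self) -> None:
        grids = [self.sst.grid, self.npp.grid]
        grids += [f.grid for f in (self.zeu, self.model_export) if f is not None]
        if any(g != grids[0] for g in grids[1:]):
            raise GridError("all export input fields must share one grid")

    @property
    def grid(self) -> GeoGrid:
        return self.sst.grid


def export_member(algorithm: str, inputs: ExportInputs) -> GriddedField:
    """One ensemble member: ratio(SST, NPP, Zeu) * NPP, or the model field.

    Valid where every required driver is valid.
    """
    if algorithm == "model":
        if inputs.model_export is None:
            raise AlgorithmError("member 'model' requires a model_export field")
        f = inputs.model_export
        return GriddedField(grid=f.grid, values=f.values.copy(), valid=f.valid.copy(),
                            units=UNITS_EXPORT, name="model")
    valid = inputs.sst.valid & inputs.npp.valid
    zeu_vals = None
    if algorithm == "dunne":
        if inputs.zeu is None:
            raise AlgorithmError("dunne algorithm requires euphotic depth (zeu)")
        valid = valid & inputs.zeu.valid
        zeu_vals = np.where(inputs.zeu.valid, inputs.zeu.values, 1.0)
    sst = np.where(valid, inputs.sst.values, 0.0)
    npp = np.where(valid, inputs.npp.values, 0.0)
    ratio = e_ratio(algorithm, sst, npp, zeu_vals)
    values = np.where(valid, ratio * npp, np.nan)
    return GriddedField(grid=inputs.grid, values=values, valid=valid,
                        units=UNITS_EXPORT, name=algorithm)


@dataclass
class ExportEnsemble:
    """Named export members plus their cell-wise valid-member mean."""

    members: dict[str, GriddedField]
    mean_export: GriddedField

    @property
    def member_names(self) -> list[str]:
        return list(self.members)


def ensemble_mean(members: dict[str, GriddedField]) -> ExportEnsemble:
    """Cell-wise arithmetic mean over the valid members at each cell.

    The mean is valid wherever at least one member is valid; cells covered
    by fewer members than the ensemble size simply average the members that
    are present.
    """
    if not members:
        raise AlgorithmError("ensemble requires at least one member")
    fields = list(members.values())
    grid = fields[0].grid
    if any(f.grid != grid for f in fields[1:]):
        raise GridError("ensemble members must share one grid")
    stack = np.stack([np.where(f.valid, f.values, 0.0) for f in fields])
    count = np.stack([f.valid for f in fields]).sum(axis=0)
    valid = count > 0
    with np.errstate(invalid="ignore"):
        mean = np.where(valid, stack.sum(axis=0) / np.maximum(count, 1), np.nan)
    mean_field = GriddedField(grid=grid, values=mean, valid=valid,
                              units=UNITS_EXPORT, name="ensemble_mean")
    return ExportEnsemble(members=dict(members), mean_export=mean_field)


def compute_ensemble(inputs: ExportInputs,
                     algorithms: tuple[str, ...] | list[str] = DEFAULT_MEMBERS) -> ExportEnsemble:
    """Run every requested algorithm and form the ensemble mean.

    ``model`` and ``dunne`` members are silently dropped when their driver
    (model_export / zeu) is absent, provided at least one member remains.
    """
    members: dict[str, GriddedField] = {}
    for name in algorithms:
        if name == "model" and inputs.model_export is None:
            continue
        if name == "dunne" and inputs.zeu is None:
            continue
        members[name] = export_member(name, inputs)
    if not members:
        raise AlgorithmError("no export member could be computed from these inputs")
    return ensemble_mean(members)


def global_range(ensemble: ExportEnsemble, areas: CellAreas) -> tuple[float, float, float]:
    """(total of mean field, min, max of per-member totals), Gt C yr^-1."""
    per_member = [global_integral(f, areas) for f in ensemble.members.values()]
    total_mean = global_integral(ensemble.mean_export, areas)
    return total_mean, min(per_member), max(per_member)


def sequestered(total_export: float, fraction: float = 0.15,
                bounds: tuple[float, float] = (0.05, 0.50)) -> tuple[float, float, float]:
    """Long-term sequestered carbon from a surface export total.

    Only a temperature-dependent fraction of exported carbon (central ~15%,
    plausible range 5-50%) stays locked in deep water or sediments on
    century-plus timescales; the rest is remineralized en route.
    """
    low, high = bounds
    if not (0 < fraction <= 1 and 0 < low <= 1 and 0 < high <= 1):
        raise ValueError("fraction and bounds must lie in (0, 1]")
    if low > high:
        raise ValueError(f"sequestration bounds inverted: {bounds}")
    return total_export * fraction, total_export * low, total_export * high
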