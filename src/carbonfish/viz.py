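"""Minimal preview plotting for gridded fields (no map projection)."""

from __future__ import annotations

from .grid import GriddedField, log_z


def plot_field(field: GriddedField, ax=None, log_z_scale: bool = False, **kwargs):
    """pcolormesh preview of a field on plain lat-lon axes.

    ``log_z_scale=True`` applies the log z-score transform first, which is
    the conventional way to display heavy-tailed effort maps.
    """
    import matplotlib.pyplot as plt

    if log_z_scale:
        field = log_z(field)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    mesh = ax.pcolormesh(field.grid.lon_edges, field.grid.lat_edges,
                         field.masked(), **kwargs)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    label = field.name or "value"
    if field.units:
        label += f" ({field.units})"
    plt.colorbar(mesh, ax=ax, label=label)
    return ax
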