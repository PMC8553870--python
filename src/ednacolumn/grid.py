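"""Vertical grid for the 1-D water column.

Depth is positive downward with ``z = 0`` at the sea surface. Cells are
uniform; concentrations live at cell centers, diffusivity and vertical
velocity at cell edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class Grid:
    """Uniform vertical grid from the surface down to ``depth_extent``.

    Attributes
    ----------
    depth_extent : float
        Total column depth in meters (default 1500).
    dz : float
        Cell thickness in meters (default 0.5).
    cell_edges : ndarray, shape (n + 1,)
        Depths of cell boundaries, surface to bottom.
    cell_centers : ndarray, shape (n,)
        Depths of cell midpoints, strictly increasing downward.
    """

    depth_extent: float
    dz: float
    cell_edges: np.ndarray = field(repr=False)
    cell_centers: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.cell_centers.size


def build_grid(depth_extent: float = 1500.0, dz: float = 0.5) -> Grid:
    """Construct a uniform vertical grid.

    ``depth_extent`` must be an exact integer multiple of ``dz``; anything
    else is a configuration error rather than a silent rounding.
    """
    if depth_extent <= 0 or dz <= 0:
        raise ConfigurationError("depth_extent and dz must be positive")
    ratio = depth_extent / dz
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(1.0, ratio):
        raise ConfigurationError(
            f"depth_extent={depth_extent} is not an integer multiple of dz={dz}"
        )
    edges = np.linspace(0.0, depth_extent, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Grid(depth_extent=float(depth_extent), dz=float(dz),
                cell_edges=edges, cell_centers=centers)
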