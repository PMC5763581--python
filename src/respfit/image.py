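"""Raster image and displacement-field containers.

Images are 2D scalar grids with a pixel spacing and a world origin
(pixel-centre convention, 0-based indices).  Displacements are expressed in
pixels of the grid they are defined on, with component 0 along axis 0
(rows) and component 1 along axis 1 (columns).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_array(obj) -> np.ndarray:
    """Accept a bare ndarray or a container with a ``.data`` attribute."""
    if hasattr(obj, "data"):
        return np.asarray(obj.data)
    return np.asarray(obj)


@dataclass
class RasterImage:
    """A 2D scalar intensity grid.

    Parameters
    ----------
    data : ndarray, shape (ny, nx)
        Intensities in arbitrary units.
    spacing : tuple of float
        Per-axis pixel size (row, column).
    origin : tuple of float
        World coordinate of the centre of pixel (0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError("RasterImage requires a 2D grid with at least one pixel per axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RasterImage intensities must be finite")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("pixel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class DisplacementField:
    """A dense per-pixel 2-vector displacement, in pixels.

    ``data`` has shape (2, ny, nx); component 0 displaces along rows.
    """

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != 2:
            raise ValueError("DisplacementField data must have shape (2, ny, nx)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacements must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]
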