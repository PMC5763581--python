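"""Cubic B-spline transformations and their exact adjoints.

A transformation is parameterized either by a dense displacement field or by
a lattice of control-point displacements (free-form deformation).  The
control-point lattice covers the image domain plus a one-point B-spline
support margin on every side; control point ``j`` along an axis sits at
pixel coordinate ``(j - 1) * spacing``.

Everything here is a *linear* map in the quantity it transports, and each
forward operation has its exact matrix transpose available:

========================  ==========================
forward                   adjoint
========================  ==========================
``evaluate_displacement``  ``project_gradient_to_cpg``
``warp_pull``              ``warp_push``
========================  ==========================

The adjoint pairs satisfy the dot-product identity to machine precision,
which the model-fitting gradients rely on.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .image import _as_array

__all__ = [
    "ControlPointGrid",
    "cubic_bspline_basis",
    "n_control_points",
    "evaluate_displacement",
    "project_gradient_to_cpg",
    "warp_pull",
    "warp_pull_with_gradient",
    "warp_push",
    "image_gradient",
]


def cubic_bspline_basis(u):
    """The four cubic B-spline basis values at fractional offset ``u``.

    Returns an array of shape ``u.shape + (4,)`` holding
    ``B1(u) = (1-u)^3/6``, ``B2(u) = (3u^3-6u^2+4)/6``,
    ``B3(u) = (-3u^3+3u^2+3u+1)/6`` and ``B4(u) = u^3/6``.
    They sum to 1 (partition of unity) and are non-negative on [0, 1].
    """
    u = np.asarray(u, dtype=float)
    b1 = (1.0 - u) ** 3 / 6.0
    b2 = (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0
    b3 = (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0
    b4 = u**3 / 6.0
    return np.stack([b1, b2, b3, b4], axis=-1)


def n_control_points(n_pixels: int, spacing: float) -> int:
    """Lattice size along one axis: covers the image plus one support margin."""
    return int(np.floor((n_pixels - 1) / spacing)) + 4


def _basis_for_coords(coords: np.ndarray, spacing: float, n_ctrl: int) -> np.ndarray:
    """Dense (len(coords), n_ctrl) B-spline basis matrix along one axis.

    ``coords`` are pixel coordinates (may be fractional).  Each row has the
    four tensor weights of the surrounding control points.
    """
    coords = np.asarray(coords, dtype=float)
    t = coords / spacing
    base = np.floor(t).astype(int)
    u = t - base
    w = cubic_bspline_basis(u)
    if base.min() < 0 or base.max() + 3 > n_ctrl - 1:
        raise ValueError("coordinates extend beyond the control-point lattice support")
    B = np.zeros((coords.size, n_ctrl))
    rows = np.arange(coords.size)
    for k in range(4):
        B[rows, base + k] = w[..., k]
    return B


@lru_cache(maxsize=128)
def _axis_basis(n_pixels: int, spacing: float) -> np.ndarray:
    nc = n_control_points(n_pixels, spacing)
    return _basis_for_coords(np.arange(n_pixels, dtype=float), spacing, nc)


@dataclass
class ControlPointGrid:
    """Cubic B-spline coefficient lattice parameterizing one transformation.

    ``coefficients`` has shape (2, ncy, ncx): 2-vector control-point
    displacements in pixels of the image grid described by ``image_shape``.
    """

    coefficients: np.ndarray
    spacing: float
    image_shape: tuple[int, int]

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.spacing < 1:
            raise ValueError("control-point spacing must be at least one pixel")
        ny, nx = self.image_shape
        want = (2, n_control_points(ny, self.spacing), n_control_points(nx, self.spacing))
        if self.coefficients.shape != want:
            raise ValueError(
                f"coefficient lattice shape {self.coefficients.shape} does not cover "
                f"image {self.image_shape}; expected {want}"
            )

    @classmethod
    def zeros(cls, image_shape: tuple[int, int], spacing: float) -> "ControlPointGrid":
        ny, nx = image_shape
        shape = (2, n_control_points(ny, spacing), n_control_points(nx, spacing))
        return cls(np.zeros(shape), float(spacing), (int(ny), int(nx)))

    @property
    def lattice_shape(self) -> tuple[int, int]:
        return self.coefficients.shape[1:]


def evaluate_displacement(cpg: ControlPointGrid, rows: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the B-spline displacement field on (a row band of) the image grid.

    The field at pixel (y, x) is the tensor-product cubic-B-spline weighted
    sum of the 4x4 surrounding control-point displacements.  Returns an
    array of shape (2, len(rows), nx); ``rows`` defaults to every row.
    """
    ny, nx = cpg.image_shape
    By = _axis_basis(ny, cpg.spacing)
    if rows is not None:
        By = By[np.asarray(rows, dtype=int)]
    Bx = _axis_basis(nx, cpg.spacing)
    c = cpg.coefficients
    return np.stack([By @ c[0] @ Bx.T, By @ c[1] @ Bx.T])


def project_gradient_to_cpg(
    pixel_gradient: np.ndarray,
    cpg: ControlPointGrid,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Exact transpose of :func:`evaluate_displacement`.

    Maps a per-pixel 2-vector gradient (shape ``(2, len(rows), nx)``) onto
    the control-point lattice: each control point receives the
    B-spline-basis-weighted sum of the pixel gradients in its support.
    """
    g = np.asarray(pixel_gradient, dtype=float)
    ny, nx = cpg.image_shape
    By = _axis_basis(ny, cpg.spacing)
    if rows is not None:
        By = By[np.asarray(rows, dtype=int)]
    Bx = _axis_basis(nx, cpg.spacing)
    if g.shape[0] != 2 or g.shape[1] != By.shape[0] or g.shape[2] != nx:
        raise ValueError(f"pixel gradient shape {g.shape} does not match the image grid")
    return np.stack([By.T @ g[0] @ Bx, By.T @ g[1] @ Bx])


# ---------------------------------------------------------------------------
# Warping (pull / push interpolation)
# ---------------------------------------------------------------------------


def _sample_positions(field: np.ndarray, rows: np.ndarray | None):
    field = np.asarray(field, dtype=float)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError("field must have shape (2, m, nx)")
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    m, nx = field.shape[1:]
    if rows is None:
        rows = np.arange(m, dtype=float)
    rows = np.asarray(rows, dtype=float)
    py = rows[:, None] + field[0]
    px = np.arange(nx, dtype=float)[None, :] + field[1]
    return py, px


def _bilinear_pieces(py, px, shape):
    """Corner indices, weights and in-bounds masks for bilinear interpolation."""
    ny, nx = shape
    y0 = np.floor(py).astype(int)
    x0 = np.floor(px).astype(int)
    wy = py - y0
    wx = px - x0
    pieces = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = y0 + dy
        xx = x0 + dx
        w = (wy if dy else 1.0 - wy) * (wx if dx else 1.0 - wx)
        inb = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        pieces.append((yy, xx, w, inb))
    return pieces, wy, wx


def _gather(image, pieces, pad):
    ny, nx = image.shape
    vals = []
    for yy, xx, _w, inb in pieces:
        v = image[np.clip(yy, 0, ny - 1), np.clip(xx, 0, nx - 1)]
        vals.append(np.where(inb, v, pad))
    return vals


def warp_pull(image, field, rows=None, pad: float = 0.0) -> np.ndarray:
    """Pull-interpolation: ``out[y, x] = image(y + field_y, x + field_x)``.

    Bilinear interpolation; sample positions outside the image take the
    ``pad`` value.  ``rows`` selects the output rows (pixel row coordinates
    of the band the field is defined on).
    """
    image = _as_array(image).astype(float)
    py, px = _sample_positions(field, rows)
    pieces, _, _ = _bilinear_pieces(py, px, image.shape)
    v00, v01, v10, v11 = _gather(image, pieces, pad)
    w = [p[2] for p in pieces]
    return w[0] * v00 + w[1] * v01 + w[2] * v10 + w[3] * v11


def warp_pull_with_gradient(image, field, rows=None, pad: float = 0.0):
    """Pull-interpolation plus the exact derivative of the sampled value
    with respect to the sample position.

    Returns ``(warped, grad)`` where ``grad`` has shape (2, m, nx) and is
    the derivative of the bilinear interpolant (piecewise constant per
    cell), so analytic cost gradients match finite differences of the
    discrete cost.
    """
    image = _as_array(image).astype(float)
    py, px = _sample_positions(field, rows)
    pieces, wy, wx = _bilinear_pieces(py, px, image.shape)
    v00, v01, v10, v11 = _gather(image, pieces, pad)
    w = [p[2] for p in pieces]
    warped = w[0] * v00 + w[1] * v01 + w[2] * v10 + w[3] * v11
    dy = (1.0 - wx) * (v10 - v00) + wx * (v11 - v01)
    dx = (1.0 - wy) * (v01 - v00) + wy * (v11 - v10)
    return warped, np.stack([dy, dx])


def warp_push(image, field, out_shape, rows=None, mass=None):
    """Push-interpolation (splatting): the exact adjoint of :func:`warp_pull`.

    Each input pixel's intensity is splatted with bilinear weights onto the
    four output pixels surrounding its pushed position ``x + field(x)``.
    Returns ``(accumulated, weights)`` where ``weights`` accumulates the
    same splat weights applied to ``mass`` (default: ones), so
    ``accumulated / weights`` is an intensity-preserving resampling.

    Out-of-bounds targets are dropped, matching pull's constant padding.
    """
    image = _as_array(image).astype(float)
    py, px = _sample_positions(field, rows)
    if image.shape != py.shape:
        raise ValueError("image must live on the same band grid as the field")
    if mass is None:
        mass = np.ones_like(image)
    accum = np.zeros(out_shape)
    wsum = np.zeros(out_shape)
    pieces, _, _ = _bilinear_pieces(py, px, out_shape)
    for yy, xx, w, inb in pieces:
        if not inb.any():
            continue
        sel = inb
        np.add.at(accum, (yy[sel], xx[sel]), (w * image)[sel])
        np.add.at(wsum, (yy[sel], xx[sel]), (w * mass)[sel])
    return accum, wsum


def image_gradient(image) -> np.ndarray:
    """Spatial intensity gradient: central differences in the interior,
    one-sided at the borders.  Shape (2, ny, nx), units intensity/pixel."""
    image = _as_array(image).astype(float)
    if min(image.shape) < 3:
        raise ValueError("image_gradient requires at least 3 pixels per axis")
    gy, gx = np.gradient(image)
    return np.stack([gy, gx])
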