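"""Image-acquisition operators A_t and their adjoints.

Four acquisition regimes are supported for 2D data, all along the row
(through-slice) axis:

``full``
    The frame is the whole image; A_t is the identity.
``slab`` / ``slice``
    The frame is a contiguous block of rows (a slab of several rows, or a
    single thin row); A_t extracts those rows.
``thick_slice``
    The frame has a lower through-slice resolution than the image: A_t
    convolves along the row axis with a Gaussian slice profile (truncated
    at +-3 sigma and renormalized to sum 1), then samples the stated
    row(s).

Internally every mode is represented as a small dense matrix ``S`` acting
on a band of image rows, so ``acquire`` is ``S @ image[band]`` and
``acquire_adjoint`` embeds ``S.T @ partial`` back into the band.  The
symmetric kernel plus zero-padded boundaries keep the operator exactly
linear, so the adjoint is the exact matrix transpose and dot-product tests
hold to machine precision.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .image import _as_array

__all__ = ["AcquisitionSpec", "acquire", "acquire_adjoint", "gaussian_profile", "FWHM_TO_SIGMA"]

#: FWHM / sigma ratio of a Gaussian: 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def gaussian_profile(sigma: float) -> np.ndarray:
    """Discrete Gaussian slice profile truncated at +-3 sigma, sum 1."""
    if sigma <= 0:
        raise ValueError("profile sigma must be positive")
    radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


@dataclass(frozen=True)
class AcquisitionSpec:
    """Per-frame description of the acquisition operator A_t.

    ``row_start``/``n_rows`` give the sampled rows (ignored for ``full``);
    ``profile_sigma`` is the Gaussian slice-profile sigma in pixels
    (``thick_slice`` only).  ``time`` records the acquisition instant of
    the frame, used to look up the matching surrogate sample.
    """

    mode: str  # full | slab | slice | thick_slice
    row_start: int = 0
    n_rows: int = 1
    profile_sigma: float | None = None
    time: float = 0.0

    def __post_init__(self):
        if self.mode not in ("full", "slab", "slice", "thick_slice"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        if self.mode == "thick_slice" and (self.profile_sigma is None or self.profile_sigma <= 0):
            raise ValueError("thick_slice requires a positive profile_sigma")

    def without_profile(self) -> "AcquisitionSpec":
        """The operator at matched resolution: row sampling without the
        slice-profile Gaussian.  Used when the reference image already has
        the dynamic data's (low) through-slice resolution, in which case
        no resolution-difference convolution belongs in A_t."""
        if self.mode != "thick_slice":
            return self
        return AcquisitionSpec("slice", self.row_start, self.n_rows, None, self.time)

    def rows(self, ny: int) -> np.ndarray:
        """The sampled row indices of the partial data within the image."""
        if self.mode == "full":
            return np.arange(ny)
        r = np.arange(self.row_start, self.row_start + self.n_rows)
        if r.min() < 0 or r.max() >= ny:
            raise ValueError(f"rows {r.min()}..{r.max()} outside image with {ny} rows")
        return r

    def operator(self, ny: int):
        """Band rows and sampling matrix: ``P = S @ image[band_rows]``."""
        return _operator(self, ny)


@lru_cache(maxsize=4096)
def _operator(spec: AcquisitionSpec, ny: int):
    rows = spec.rows(ny)
    if spec.mode in ("full", "slab", "slice"):
        band = rows
        S = np.eye(rows.size)
        return band, S
    # thick_slice: band covers the Gaussian support of every sampled row
    kernel = gaussian_profile(spec.profile_sigma)
    radius = kernel.size // 2
    band = np.arange(max(rows.min() - radius, 0), min(rows.max() + radius, ny - 1) + 1)
    S = np.zeros((rows.size, band.size))
    for i, r in enumerate(rows):
        offsets = band - r
        inside = np.abs(offsets) <= radius
        S[i, inside] = kernel[offsets[inside] + radius]
    return band, S


def acquire(image, spec: AcquisitionSpec) -> np.ndarray:
    """Simulate the acquisition of one frame of (partial) data from a full
    image: P_t = A_t(I_t).  Noise is the simulator's business, not this
    operator's."""
    image = _as_array(image).astype(float)
    band, S = spec.operator(image.shape[0])
    return S @ image[band]


def acquire_adjoint(partial, spec: AcquisitionSpec, ny: int) -> np.ndarray:
    """The adjoint A*_t: embed partial data back into full-image space.

    Rows are placed at their acquisition location (zeros elsewhere); for
    thick slices the embedding is spread with the same Gaussian profile
    used by :func:`acquire`.  Exact matrix transpose of ``acquire``.
    """
    partial = np.asarray(partial, dtype=float)
    band, S = spec.operator(ny)
    if partial.shape[0] != S.shape[0]:
        raise ValueError(
            f"partial data has {partial.shape[0]} rows but the spec samples {S.shape[0]}"
        )
    out = np.zeros((ny, partial.shape[1]))
    out[band] = S.T @ partial
    return out
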