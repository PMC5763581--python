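"""Surrogate signals and correspondence models.

A correspondence model relates the motion parameters at time ``t`` to
respiratory surrogate signals through a linear combination of terms
pre-computed from the signals:

    M_t = sum_n R_n * phi_n(S_t)

where the ``R_n`` are coefficient sets shaped like the motion
parameterization (a control-point lattice, or a dense field) and the basis
``phi_n`` depends on the model kind:

``linear_sdot``
    phi = [s, s_dot, 1] - a linear model on the signal value and its
    temporal derivative, with a constant offset.  Captures both intra-cycle
    (hysteresis) and inter-cycle variation.
``linear_sdot_no_offset``
    phi = [s, s_dot] - the same linear model without the constant term.
    Used when the reference image is an MCIR: with mean-zero surrogates the
    reconstruction already sits at the average anatomical position, and a
    free static term would be able to absorb spurious "deblurring"
    deformations of the motion-blurred reference.
``poly2``
    phi = [s^2, s, 1] - second-order polynomial in one signal.
``periodic_bspline``
    phi_n = B_i(j) with i = (floor(N_r * theta) + n - 2) mod N_r and
    j = N_r * theta - floor(N_r * theta), where theta in [0, 1) is the
    respiratory phase and B_1..B_4 are the cubic B-spline basis
    polynomials.  Periodic in phase; models intra-cycle variation only.
``constant``
    phi = [1] - a single transformation shared by all frames; with one
    frame this reduces the fit to an ordinary pairwise registration.

Because the model is linear in R, the gradient of the motion parameters
with respect to each coefficient set is simply ``dM_t/dR_n = phi_n``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MODEL_KINDS = ("linear_sdot", "linear_sdot_no_offset", "poly2", "periodic_bspline", "constant")


@dataclass
class SurrogateSeries:
    """Respiratory surrogate samples: times, signal values, and optionally a
    temporal derivative and a respiratory phase in [0, 1)."""

    times: np.ndarray
    values: np.ndarray  # (N_i, N_s)
    derivative: np.ndarray | None = None
    phase: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.times.size > 1:
            self.values = self.values.T
        if self.times.size < 2:
            raise ValueError("a surrogate series needs at least two samples")
        if self.values.shape[0] != self.times.size:
            raise ValueError("values must have one row per sample time")
        if self.derivative is not None:
            self.derivative = np.atleast_2d(np.asarray(self.derivative, dtype=float))
            if self.derivative.shape[0] == 1 and self.times.size > 1:
                self.derivative = self.derivative.T
            if self.derivative.shape != self.values.shape:
                raise ValueError("derivative shape must match values")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)

    def __len__(self) -> int:
        return self.times.size


def normalize_surrogate(series: SurrogateSeries) -> SurrogateSeries:
    """Subtract each signal column's mean so every column has mean zero.

    The scale is left unchanged.  With mean-zero signals a motion model
    without offset maps the reference image to the *average* position of
    the anatomy, which is where an MCIR reference sits.
    """
    values = series.values - series.values.mean(axis=0, keepdims=True)
    if np.any(series.values.std(axis=0) == 0):
        warnings.warn(
            "surrogate column with zero variance: the correspondence model "
            "will be degenerate in that signal", stacklevel=2,
        )
    return replace(series, values=values)


def temporal_derivative(series: SurrogateSeries) -> SurrogateSeries:
    """Fill the temporal-derivative field by finite differences.

    Central differences on interior samples and one-sided differences at
    the ends, honouring non-uniform sample spacing.
    """
    t = series.times
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate sample times: derivative undefined")
    if np.any(np.diff(t) < 0):
        raise ValueError("sample times must be monotone increasing")
    deriv = np.gradient(series.values, t, axis=0)
    return replace(series, derivative=deriv)


def periodic_bspline_basis(theta: float, n_terms: int) -> np.ndarray:
    """Periodic cubic B-spline basis on the respiratory phase.

    With the phase split as ``N*theta = k + j`` (interval ``k``, fractional
    offset ``j``), control point ``n`` (1-indexed) carries the segment
    polynomial ``B_m(j)`` with ``m = ((n - k - 2) mod N) + 1`` when
    ``m <= 4`` and zero otherwise, where B_1..B_4 are the four cubic
    B-spline segment polynomials.  The segment index *decreases* as the
    interval advances, which is what makes each phi_n a continuous
    (periodized, shifted) copy of the cubic B-spline bump: B_m(1) equals
    B_{m-1}(0) at every knot crossing and across the theta = 0 wrap.
    The weights are non-negative and sum to exactly 1 for any phase, and
    phi(0) = [0, 1/6, 4/6, 1/6] for N = 4.
    """
    if n_terms < 4:
        raise ValueError("a periodic B-spline model needs at least 4 control points")
    theta = float(theta)
    if not 0.0 <= theta < 1.0:
        warnings.warn(f"phase {theta} outside [0,1); wrapping modulo 1", stacklevel=2)
        theta = theta % 1.0
    x = n_terms * theta
    k = int(np.floor(x))
    j = x - k
    # the four cubic B-spline segment polynomials, 1-indexed as B_1..B_4
    b = (
        (1.0 - j) ** 3 / 6.0,
        (3.0 * j**3 - 6.0 * j**2 + 4.0) / 6.0,
        (-3.0 * j**3 + 3.0 * j**2 + 3.0 * j + 1.0) / 6.0,
        j**3 / 6.0,
    )
    phi = np.zeros(n_terms)
    for n in range(1, n_terms + 1):
        m = (n - k - 2) % n_terms
        if m < 4:
            phi[n - 1] = b[m]
    return phi


def basis(kind: str, values=None, derivative=None, phase=None, n_terms: int | None = None) -> np.ndarray:
    """The basis vector phi(S_t) for one surrogate sample.

    Parameters
    ----------
    kind : str
        One of ``linear_sdot``, ``poly2``, ``periodic_bspline``, ``constant``.
    values, derivative : array-like
        Signal value(s) and temporal derivative(s) at time t.
    phase : float
        Respiratory phase in [0, 1) (periodic model only).
    n_terms : int
        Number of periodic control points (default 4).
    """
    if kind == "linear_sdot":
        s = np.atleast_1d(values)[0]
        if derivative is None:
            raise ValueError("linear_sdot requires the temporal derivative")
        sdot = np.atleast_1d(derivative)[0]
        return np.array([s, sdot, 1.0])
    if kind == "linear_sdot_no_offset":
        s = np.atleast_1d(values)[0]
        if derivative is None:
            raise ValueError("linear_sdot_no_offset requires the temporal derivative")
        sdot = np.atleast_1d(derivative)[0]
        return np.array([s, sdot])
    if kind == "poly2":
        s = float(np.atleast_1d(values)[0])
        return np.array([s * s, s, 1.0])
    if kind == "periodic_bspline":
        if phase is None:
            raise ValueError("periodic_bspline requires a respiratory phase")
        return periodic_bspline_basis(phase, n_terms or 4)
    if kind == "constant":
        return np.array([1.0])
    raise ValueError(f"unknown correspondence model kind {kind!r}")


def n_model_terms(kind: str, n_terms: int | None = None) -> int:
    if kind == "periodic_bspline":
        return n_terms or 4
    return {"linear_sdot": 3, "linear_sdot_no_offset": 2, "poly2": 3, "constant": 1}[kind]


def basis_matrix(kind: str, series: SurrogateSeries, n_terms: int | None = None) -> np.ndarray:
    """Stack basis vectors for every sample of a series: shape (N_i, N_r)."""
    if kind.startswith("linear_sdot") and series.derivative is None:
        series = temporal_derivative(series)
    rows = []
    for i in range(len(series)):
        rows.append(
            basis(
                kind,
                values=series.values[i],
                derivative=None if series.derivative is None else series.derivative[i],
                phase=None if series.phase is None else series.phase[i],
                n_terms=n_terms,
            )
        )
    return np.asarray(rows)


@dataclass
class CorrespondenceModel:
    """A fitted (or ground-truth) correspondence model.

    ``coefficients`` stacks the N_r coefficient sets, each shaped like one
    motion parameterization: ``(N_r, 2, ncy, ncx)`` for control-point
    lattices, or ``(N_r, 2, ny, nx)`` for dense per-pixel maps (the phantom
    convention).  ``cpg_spacing`` is None for dense models.
    """

    kind: str
    coefficients: np.ndarray
    cpg_spacing: float | None = None
    image_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.coefficients.ndim != 4 or self.coefficients.shape[1] != 2:
            raise ValueError("coefficients must have shape (N_r, 2, ny, nx)")
        if self.n_terms != n_model_terms(self.kind, self.coefficients.shape[0]):
            raise ValueError(f"{self.kind} expects {n_model_terms(self.kind)} coefficient sets")

    @property
    def n_terms(self) -> int:
        return self.coefficients.shape[0]

    @property
    def is_dense(self) -> bool:
        return self.cpg_spacing is None

    @property
    def includes_offset(self) -> bool:
        return self.kind in ("linear_sdot", "poly2")  # no-offset variant: MCIR references sit at the mean position

    def motion(self, phi: np.ndarray) -> np.ndarray:
        return model_motion(self.coefficients, phi)


def model_motion(coefficients: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """M_t = sum_n R_n * phi_n: the motion parameters for one basis vector.

    The gradient contract is dM_t/dR_n = phi_n (a scalar multiplier per
    coefficient set), which is what makes the unified fit's chain rule
    cheap.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1 or phi.size != coefficients.shape[0]:
        raise ValueError(
            f"basis vector length {phi.size} does not match {coefficients.shape[0]} coefficient sets"
        )
    return np.tensordot(phi, coefficients, axes=(0, 0))
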