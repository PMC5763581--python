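"""Unified model fitting: registration and correspondence-model estimation
in a single optimization.

Instead of registering each dynamic frame independently and regressing the
resulting transformations against the surrogate signals, the correspondence
model coefficients R are optimized directly on all frames at once.  The
per-frame cost is the sum of squared differences (SSD) between the measured
(partial) data and data simulated from the reference image:

    C_t(P_t, I_0, M_t) = || P_t - A_t(T(I_0, M_t)) ||^2,   M_t = sum_n R_n phi_n(S_t)

and the total cost is C_total = sum_t C_t.  The gradient follows the chain
rule through exact adjoints: the SSD gradient in partial-data space is
mapped to full-image space by A*_t, multiplied by the sampled spatial
gradient of the warped reference, projected onto the control-point lattice
by the B-spline transpose, and finally scaled by each basis value phi_n.
Every link is the exact derivative of the discrete forward computation, so
the analytic gradient matches finite differences of the cost.

Minimization uses nonlinear conjugate gradient (scipy's Polak-Ribiere CG
with Wolfe line search), optionally inside a multi-resolution pyramid for
full-image data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator

from .acquisition import AcquisitionSpec
from .correspondence import (
    CorrespondenceModel,
    SurrogateSeries,
    basis_matrix,
    normalize_surrogate,
    temporal_derivative,
)
from .image import _as_array
from .transform import ControlPointGrid, _axis_basis, n_control_points

__all__ = ["FitConfig", "ssd_and_gradient", "frame_cost_gradient", "fit_model", "SurrogateMotionModel"]


@dataclass
class FitConfig:
    """Tunable settings of the unified fit.

    ``cpg_spacing`` is the B-spline control-point spacing in pixels (same
    in both directions).  ``levels`` sets the depth of the coarse-to-fine
    image pyramid (partial-data frames are downsampled along with the
    reference; the spacing in pixels is kept, so it doubles physically per
    coarser level).  ``tol`` is the relative gradient-norm stopping
    tolerance; ``max_iterations`` bounds the CG iterations per level and,
    since no constraint term is used, doubles as the implicit noise
    regularizer.  ``pad`` is the intensity assumed outside the reference
    image when warping.
    """

    cpg_spacing: float = 5.0
    levels: int = 1
    max_iterations: int = 100
    tol: float = 1e-3
    pad: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cpg_spacing < 1:
            raise ValueError("cpg_spacing must be >= 1 pixel")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


def ssd_and_gradient(P, P_sim):
    """SSD cost and its gradient with respect to the simulated data.

    cost = sum (P_sim - P)^2,  d cost / d P_sim = 2 (P_sim - P).
    """
    P = np.asarray(P, dtype=float)
    P_sim = np.asarray(P_sim, dtype=float)
    if P.shape != P_sim.shape:
        raise ValueError(f"shape mismatch: measured {P.shape} vs simulated {P_sim.shape}")
    resid = P_sim - P
    return float((resid * resid).sum()), 2.0 * resid


class _Problem:
    """Precomputed geometry shared by every cost evaluation of one fit.

    Frames sharing the same acquisition geometry (band of rows, sampling
    matrix) are batched, so slice datasets where every row position is
    imaged many times cost one set of array operations per position
    rather than per frame.
    """

    def __init__(self, frames, specs, Phi, I0, cpg_spacing, pad):
        self.I0 = _as_array(I0).astype(float)
        ny, nx = self.I0.shape
        self.shape = (ny, nx)
        self.spacing = float(cpg_spacing)
        self.ncy = n_control_points(ny, self.spacing)
        self.ncx = n_control_points(nx, self.spacing)
        self.By = _axis_basis(ny, self.spacing)
        self.Bx = _axis_basis(nx, self.spacing)
        self.Phi = np.asarray(Phi, dtype=float)
        self.n_terms = self.Phi.shape[1]
        self.pad = float(pad)
        self.n_coef = 2 * self.ncy * self.ncx
        if len(frames) != self.Phi.shape[0]:
            raise ValueError("one surrogate sample (basis row) is required per frame")
        by_geom: dict = {}
        for t, spec in enumerate(specs):
            key = (spec.mode, spec.row_start, spec.n_rows, spec.profile_sigma)
            by_geom.setdefault(key, []).append(t)
        self.groups = []
        for key, idx in by_geom.items():
            spec = specs[idx[0]]
            band, S = spec.operator(ny)
            identity = spec.mode in ("full", "slab", "slice")
            P = np.stack([np.asarray(frames[t], dtype=float) for t in idx])
            self.groups.append({
                "idx": np.asarray(idx), "band": band, "S": S, "identity": identity,
                "Byb": self.By[band], "P": P,
            })

    def _pull_grad_batch(self, fy, fx, band):
        """Batched bilinear pull + exact sample-position derivative.

        ``fy``/``fx`` have shape (G, m, nx); returns warped values and the
        two derivative components with the same shape.
        """
        ny, nx = self.I0.shape
        py = band[None, :, None] + fy
        px = np.arange(nx, dtype=float)[None, None, :] + fx
        y0 = np.floor(py).astype(int)
        x0 = np.floor(px).astype(int)
        wy = py - y0
        wx = px - x0
        vals = []
        for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
            yy = y0 + dy
            xx = x0 + dx
            inb = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
            v = self.I0[np.clip(yy, 0, ny - 1), np.clip(xx, 0, nx - 1)]
            vals.append(np.where(inb, v, self.pad))
        v00, v01, v10, v11 = vals
        warped = ((1 - wy) * (1 - wx) * v00 + (1 - wy) * wx * v01
                  + wy * (1 - wx) * v10 + wy * wx * v11)
        gy = (1 - wx) * (v10 - v00) + wx * (v11 - v01)
        gx = (1 - wy) * (v01 - v00) + wy * (v11 - v10)
        return warped, gy, gx

    def cost_grad(self, x):
        R = x.reshape(self.n_terms, self.n_coef)
        M_all = (self.Phi @ R).reshape(-1, 2, self.ncy, self.ncx)
        grad = np.zeros_like(R)
        cost = 0.0
        BxT = self.Bx.T
        for grp in self.groups:
            idx, Byb, S = grp["idx"], grp["Byb"], grp["S"]
            Mg = M_all[idx]
            fy = np.matmul(np.matmul(Byb, Mg[:, 0]), BxT)
            fx = np.matmul(np.matmul(Byb, Mg[:, 1]), BxT)
            warped, gy, gx = self._pull_grad_batch(fy, fx, grp["band"].astype(float))
            P_sim = warped if grp["identity"] else np.einsum("ob,gbx->gox", S, warped)
            resid = P_sim - grp["P"]
            c = float((resid * resid).sum())
            if not np.isfinite(c):
                raise FloatingPointError(f"non-finite cost at frame {idx[0]}")
            cost += c
            dP = 2.0 * resid
            dI = dP if grp["identity"] else np.einsum("ob,gox->gbx", S, dP)
            g_cpg_y = np.matmul(np.matmul(Byb.T, dI * gy), self.Bx)
            g_cpg_x = np.matmul(np.matmul(Byb.T, dI * gx), self.Bx)
            g_flat = np.concatenate(
                [g_cpg_y.reshape(len(idx), -1), g_cpg_x.reshape(len(idx), -1)], axis=1
            )
            grad += self.Phi[idx].T @ g_flat
        return cost, grad.ravel()


def frame_cost_gradient(t, P_t, I0, model: CorrespondenceModel, surrogates: SurrogateSeries,
                        spec: AcquisitionSpec, pad: float = 0.0):
    """Cost and coefficient gradient contributed by a single frame.

    Follows the chain phi(S_t) -> M_t -> warp -> acquire -> SSD and its
    exact adjoint path back to dC_t/dR.  Returns ``(C_t, grad)`` with
    ``grad`` shaped like ``model.coefficients``.
    """
    if model.is_dense:
        raise ValueError("frame_cost_gradient requires a control-point-parameterized model")
    Phi = basis_matrix(model.kind, surrogates, n_terms=model.n_terms)
    prob = _Problem([P_t], [spec], Phi[t : t + 1], I0, model.cpg_spacing, pad)
    # re-index: the single-frame problem uses basis row t with its own frame
    prob.Phi = Phi[t : t + 1]
    try:
        cost, grad = prob.cost_grad(model.coefficients.ravel())
    except FloatingPointError as err:
        raise FloatingPointError(f"frame {t}: {err}") from err
    return cost, grad.reshape(model.coefficients.shape)


def total_cost(frames, specs, Phi, I0, model_coefficients, cpg_spacing, pad=0.0):
    """C_total = sum_t C_t for a coefficient stack (no gradient)."""
    prob = _Problem(frames, specs, Phi, I0, cpg_spacing, pad)
    cost, _ = prob.cost_grad(np.asarray(model_coefficients, dtype=float).ravel())
    return cost


# ---------------------------------------------------------------------------
# multi-resolution helpers
# ---------------------------------------------------------------------------


def _downsample_image(img: np.ndarray, times: int) -> np.ndarray:
    for _ in range(times):
        img = ndimage.gaussian_filter(img, 1.0, mode="nearest")[::2, ::2]
    return img


def _downsample_partial(P: np.ndarray, spec: AcquisitionSpec, times: int, ny_l: int):
    """Bring one frame of partial data to pyramid level ``times``.

    Columns (and slab rows) are smoothed and decimated like the reference
    image; row positions map to the coarse grid by division (rounded for
    odd offsets - exact again at the finest level).  The thick-slice
    profile sigma scales with the grid.
    """
    P = np.asarray(P, dtype=float)
    f = 2**times
    for _ in range(times):
        P = ndimage.gaussian_filter1d(P, 1.0, axis=1, mode="nearest")[:, ::2]
        if P.shape[0] >= 2:
            P = ndimage.gaussian_filter1d(P, 1.0, axis=0, mode="nearest")[::2]
    if spec.mode == "full":
        return P, AcquisitionSpec("full", time=spec.time)
    n_rows = P.shape[0]
    row = int(round(spec.row_start / f))
    row = max(0, min(row, ny_l - n_rows))
    sigma = spec.profile_sigma
    if sigma is not None:
        sigma = max(sigma / f, 0.4)
    return P, AcquisitionSpec(spec.mode, row_start=row, n_rows=n_rows,
                              profile_sigma=sigma, time=spec.time)


def _refine_cpg(coef: np.ndarray, old_spacing: float, new_spacing: float,
                image_shape: tuple[int, int]) -> np.ndarray:
    """Transfer coefficient sets between lattices of different spacing.

    Each coefficient set is mapped to the displacement field it induces on
    the image grid and the new lattice is fitted to that field by least
    squares (separable pseudo-inverse), so the refined model starts from
    (numerically) the same transformation.
    """
    ny, nx = image_shape
    By_o, Bx_o = _axis_basis(ny, old_spacing), _axis_basis(nx, old_spacing)
    By_n, Bx_n = _axis_basis(ny, new_spacing), _axis_basis(nx, new_spacing)
    Py, Px = np.linalg.pinv(By_n), np.linalg.pinv(Bx_n)
    out = np.empty((coef.shape[0], 2, By_n.shape[1], Bx_n.shape[1]))
    for n in range(coef.shape[0]):
        for c in range(2):
            field = By_o @ coef[n, c] @ Bx_o.T
            out[n, c] = Py @ field @ Px.T
    return out


def _resize_lattice(coef: np.ndarray, new_shape: tuple[int, int]) -> np.ndarray:
    """Resample a coefficient lattice onto the lattice of a 2x finer image.

    Control point ``j`` sits at pixel coordinate ``(j - 1) * spacing``; when
    the pixel grid is refined by 2 (same spacing in pixels), fine-lattice
    index ``j'`` therefore lands at coarse-lattice index ``(j' - 1)/2 + 1``.
    """
    out = np.empty((coef.shape[0], coef.shape[1]) + tuple(new_shape))
    gy = (np.arange(new_shape[0]) - 1.0) / 2.0 + 1.0
    gx = (np.arange(new_shape[1]) - 1.0) / 2.0 + 1.0
    coords = np.meshgrid(gy, gx, indexing="ij")
    for n in range(coef.shape[0]):
        for c in range(2):
            out[n, c] = ndimage.map_coordinates(coef[n, c], coords, order=1, mode="nearest")
    return out


def fit_model(
    frames,
    specs,
    surrogates: SurrogateSeries,
    I0,
    kind: str = "linear_sdot",
    config: FitConfig | None = None,
    n_terms: int | None = None,
    init: np.ndarray | None = None,
    gtol_abs: float | None = None,
):
    """Fit a correspondence model to dynamic (partial) image data.

    Minimizes the summed SSD over all frames by nonlinear conjugate
    gradient.  For full-image data a coarse-to-fine pyramid (downsampling
    by 2 per level) is used, with coefficients upsampled between levels;
    partial data are fitted at native resolution.

    Returns ``(model, info)`` where ``info`` carries the per-level cost
    traces (non-increasing within each level) and iteration counts.

    A supplied ``init`` warm-starts the coefficients (e.g. from a previous
    alternation round); ``gtol_abs`` fixes the gradient stopping threshold
    absolutely, which keeps warm-started refits from over-polishing.
    """
    config = config or FitConfig()
    specs = list(specs)
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 1:
        raise ValueError("at least one frame is required")
    if len(frames) != len(specs):
        raise ValueError("one AcquisitionSpec is required per frame")
    I0 = _as_array(I0).astype(float)
    if surrogates is None:
        if kind != "constant":
            raise ValueError(f"kind {kind!r} requires a surrogate series")
        Phi = np.ones((len(frames), 1))  # pairwise registration: phi = [1]
    else:
        Phi = basis_matrix(kind, surrogates, n_terms=n_terms)
    nr = Phi.shape[1]

    # image pyramid (full and partial data alike); do not shrink below ~4
    # control spans, and refine warm starts at the target resolution only
    levels = config.levels
    while levels > 1 and min(I0.shape) // 2 ** (levels - 1) < 4 * config.cpg_spacing:
        levels -= 1
    if init is not None:
        levels = 1

    x = None
    traces: list[list[float]] = []
    n_iter = 0
    result = None
    for lev in reversed(range(levels)):
        I0_l = _downsample_image(I0, lev)
        if lev:
            pairs = [_downsample_partial(P, s, lev, I0_l.shape[0])
                     for P, s in zip(frames, specs)]
            frames_l = [p[0] for p in pairs]
            specs_l = [p[1] for p in pairs]
        else:
            frames_l, specs_l = frames, specs
        prob = _Problem(frames_l, specs_l, Phi, I0_l, config.cpg_spacing, config.pad)
        shape_c = (prob.ncy, prob.ncx)
        if x is None:
            x0 = (np.zeros((nr, 2) + shape_c) if init is None else np.asarray(init, float)).ravel()
            if x0.size != nr * prob.n_coef:
                raise ValueError("init coefficients do not match the lattice shape")
        else:
            x0 = (2.0 * _resize_lattice(x.reshape(nr, 2, *prev_shape), shape_c)).ravel()

        c0, g0 = prob.cost_grad(x0)
        gtol = gtol_abs if gtol_abs is not None else max(config.tol * np.abs(g0).max(), 1e-12)
        trace = [c0]
        cache: dict[bytes, float] = {}

        def fun(v, _prob=prob, _cache=cache):
            c, g = _prob.cost_grad(v)
            _cache[v.tobytes()] = c
            return c, g

        def cb(v, _cache=cache, _trace=trace):
            _trace.append(_cache.get(v.tobytes(), _trace[-1]))
            _cache.clear()

        result = optimize.minimize(
            fun, x0, jac=True, method="CG", callback=cb,
            options={"maxiter": config.max_iterations, "gtol": gtol},
        )
        x = result.x
        n_iter += result.nit
        traces.append(trace)
        prev_shape = shape_c

    model = CorrespondenceModel(
        kind=kind,
        coefficients=x.reshape(nr, 2, prev_shape[0], prev_shape[1]),
        cpg_spacing=config.cpg_spacing,
        image_shape=I0.shape,
    )
    info = {
        "cost_traces": traces,
        "final_cost": float(result.fun),
        "n_iter": n_iter,
        "message": result.message,
        "gtol": gtol,
    }
    return model, info


class SurrogateMotionModel(BaseEstimator):
    """Surrogate-driven respiratory motion model, unified-fit estimator.

    Fits a correspondence model ``M_t = sum_n R_n phi_n(S_t)`` (B-spline
    control-point displacements as motion parameters) directly to dynamic
    full or partial image data, given a reference-state image.

    Parameters
    ----------
    kind : {'linear_sdot', 'poly2', 'periodic_bspline', 'constant'}
        Correspondence model family.
    cpg_spacing : float
        B-spline control-point spacing in pixels.
    levels : int
        Multi-resolution pyramid depth (full-image data only).
    max_iter : int
        Conjugate-gradient iterations per level.
    tol : float
        Relative gradient-norm stopping tolerance.
    pad : float
        Intensity assumed outside the reference image when warping.
    normalize : bool
        Normalize the surrogate signals to mean zero before fitting.
    n_terms : int or None
        Periodic B-spline control points (default 4).

    Attributes
    ----------
    model_ : CorrespondenceModel
        The fitted coefficient stack.
    cost_trace_ : list of list of float
        Per-level cost traces (non-increasing within a level).
    final_cost_ : float
    n_iter_ : int
    """

    def __init__(self, kind="linear_sdot", cpg_spacing=5.0, levels=1, max_iter=100,
                 tol=1e-3, pad=0.0, normalize=True, n_terms=None):
        self.kind = kind
        self.cpg_spacing = cpg_spacing
        self.levels = levels
        self.max_iter = max_iter
        self.tol = tol
        self.pad = pad
        self.normalize = normalize
        self.n_terms = n_terms

    def _prepare_surrogate(self, surrogate) -> SurrogateSeries:
        if not isinstance(surrogate, SurrogateSeries):
            values = np.asarray(surrogate, dtype=float)
            surrogate = SurrogateSeries(times=np.arange(len(values), dtype=float), values=values)
        if self.normalize:
            surrogate = normalize_surrogate(surrogate)
        if surrogate.derivative is None and self.kind.startswith("linear_sdot"):
            surrogate = temporal_derivative(surrogate)
        return surrogate

    def fit(self, frames, surrogate=None, *, specs=None, reference=None, init=None, gtol_abs=None):
        """Fit the model to frames + surrogate samples.

        ``frames`` is a sequence of 2D arrays (one per time-point);
        ``specs`` the matching acquisition operators (default: full
        frames); ``reference`` the reference-state image I_0 (required).
        """
        frames = [_as_array(f) for f in frames]
        if reference is None:
            raise ValueError("a reference-state image is required (or use MotionCompensatedReconstructor)")
        if specs is None:
            specs = [AcquisitionSpec("full", time=float(t)) for t in range(len(frames))]
        if surrogate is not None:
            surrogate = self._prepare_surrogate(surrogate)
        elif self.kind != "constant":
            raise ValueError(f"kind {self.kind!r} requires surrogate samples")
        cfg = FitConfig(
            cpg_spacing=self.cpg_spacing, levels=self.levels,
            max_iterations=self.max_iter, tol=self.tol, pad=self.pad,
        )
        self.model_, info = fit_model(
            frames, specs, surrogate, reference, kind=self.kind, config=cfg,
            n_terms=self.n_terms, init=init, gtol_abs=gtol_abs,
        )
        self.surrogate_ = surrogate
        self.reference_ = _as_array(reference)
        self.cost_trace_ = info["cost_traces"]
        self.final_cost_ = info["final_cost"]
        self.n_iter_ = info["n_iter"]
        return self

    def predict(self, surrogate=None):
        """Displacement fields predicted for surrogate samples.

        Returns an array (N, 2, ny, nx) of dense per-pixel displacements on
        the reference grid.  With no argument, predicts at the fitted
        surrogate samples.
        """
        from .correspondence import basis_matrix as _bm

        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        series = self.surrogate_ if surrogate is None else self._prepare_surrogate(surrogate)
        if series is None:  # constant model: one shared transformation
            return np.stack([self.predict_field(np.ones(1))])
        Phi = _bm(self.kind, series, n_terms=self.model_.n_terms)
        return np.stack([self.predict_field(phi) for phi in Phi])

    def predict_field(self, phi) -> np.ndarray:
        """Dense displacement field for one basis vector."""
        from .transform import evaluate_displacement

        M = self.model_.motion(np.asarray(phi, dtype=float))
        cpg = ControlPointGrid(M, self.model_.cpg_spacing, self.model_.image_shape)
        return evaluate_displacement(cpg)
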