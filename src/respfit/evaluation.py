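"""Quantitative assessment of fitted motion and reconstructions.

* Displacement Field Error (DFE): the per-pixel 2D Euclidean distance
  between the true and estimated displacement fields, pooled over every
  masked pixel of every time-point.  A no-motion baseline is obtained by
  passing zero estimated fields.
* Image agreement: per-pixel absolute intensity differences and the
  Pearson correlation coefficient between a reconstruction and the true
  image.
* Landmark error: snap-to-voxel convention - each reference landmark is
  propagated by the model field, rounded to the nearest voxel centre, and
  its Euclidean distance to the (optionally also snapped) target landmark
  is reported in millimetres.

Percentiles use linear interpolation between order statistics.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .image import _as_array

__all__ = ["dfe_stats", "image_agreement", "landmark_error", "model_dfe", "pooled_stats"]


def pooled_stats(values: np.ndarray):
    """(mean, std, 95th percentile) of a pooled 1D sample."""
    values = np.asarray(values, dtype=float)
    return float(values.mean()), float(values.std()), float(np.percentile(values, 95))


def dfe_stats(true_fields, est_fields, masks):
    """Pooled displacement-field-error statistics.

    Parameters are iterables (one entry per time-point) of dense fields
    with shape (2, ny, nx) and boolean masks; the per-pixel Euclidean
    distances of every masked pixel of every frame are pooled into a
    single sample.  Returns ``(mean, std, p95)`` in field units (pixels).
    """
    chunks = []
    n_frames = 0
    for f_true, f_est, mask in zip(true_fields, est_fields, masks):
        f_true = np.asarray(f_true, dtype=float)
        f_est = np.asarray(f_est, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if f_true.shape != f_est.shape or mask.shape != f_true.shape[1:]:
            raise ValueError("per-frame field/mask shapes do not match")
        d = np.hypot(f_true[0] - f_est[0], f_true[1] - f_est[1])[mask]
        # float32 keeps the pooled sample compact for slice datasets with
        # thousands of frames without visibly moving the statistics
        chunks.append(d.astype(np.float32))
        n_frames += 1
    if n_frames == 0 or sum(c.size for c in chunks) == 0:
        raise ValueError("empty mask union: no pixels to pool")
    return pooled_stats(np.concatenate(chunks))


def image_agreement(recon, reference, mask=None):
    """Absolute-difference statistics and Pearson correlation over a mask.

    Returns ``(abs_mean, abs_std, abs_p95, pearson_r)``; ``r`` is NaN when
    either image is constant over the mask (correlation undefined).
    """
    a = _as_array(recon).astype(float)
    b = _as_array(reference).astype(float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    av, bv = a[mask], b[mask]
    diff = np.abs(av - bv)
    if av.std() == 0 or bv.std() == 0:
        warnings.warn("constant image: correlation coefficient undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(stats.pearsonr(av, bv).statistic)
    m, s, p = pooled_stats(diff)
    return m, s, p, r


def landmark_error(landmarks_ref, landmarks_target, field=None, voxel_size=(1.0, 1.0),
                   snap_target: bool = True):
    """Snap-to-voxel landmark error statistics, in millimetres.

    ``landmarks_*`` are (N, 2) arrays of (row, col) pixel coordinates in
    the reference and target images.  Each reference landmark is displaced
    by the model ``field`` (dense, (2, ny, nx); linearly interpolated; None
    measures the raw motion magnitude), snapped to the nearest voxel
    centre, and compared with the (by default also snapped) target
    landmark.  Landmarks whose propagated position leaves the field domain
    are excluded with a warning.
    """
    ref = np.atleast_2d(np.asarray(landmarks_ref, dtype=float))
    tgt = np.atleast_2d(np.asarray(landmarks_target, dtype=float))
    if ref.shape != tgt.shape or ref.shape[1] != 2:
        raise ValueError("landmark lists must be matched (N, 2) arrays")
    if field is not None:
        field = np.asarray(field, dtype=float)
        ny, nx = field.shape[1:]
        inside = (ref[:, 0] >= 0) & (ref[:, 0] <= ny - 1) & (ref[:, 1] >= 0) & (ref[:, 1] <= nx - 1)
        if not inside.all():
            warnings.warn(f"excluding {int((~inside).sum())} landmark(s) outside the field domain",
                          stacklevel=2)
            ref, tgt = ref[inside], tgt[inside]
        from scipy.ndimage import map_coordinates

        disp = np.stack([
            map_coordinates(field[c], [ref[:, 0], ref[:, 1]], order=1, mode="nearest")
            for c in range(2)
        ], axis=1)
        moved = ref + disp
    else:
        moved = ref
    moved = np.round(moved)
    if snap_target:
        tgt = np.round(tgt)
    vz = np.asarray(voxel_size, dtype=float)
    dist = np.linalg.norm((moved - tgt) * vz[None, :], axis=1)
    if dist.size == 0:
        raise ValueError("no landmarks left to evaluate")
    return pooled_stats(dist)


def model_dfe(dataset, model=None, frame_stride: int = 1):
    """Pooled DFE of a fitted model against a phantom dataset's ground truth.

    ``model=None`` gives the no-motion baseline.  Streams frames and pools
    distances in float32 to keep memory flat for slice datasets;
    ``frame_stride`` subsamples time-points.  Returns ``(mean, std, p95)``
    in pixels.
    """
    if model is not None:
        from .correspondence import basis_matrix
        from .mcir import _model_band_field

        Phi = basis_matrix(model.kind, dataset.surrogate, n_terms=model.n_terms)
        field_fn = _model_band_field(model, Phi, dataset.shape)
        rows = np.arange(dataset.shape[0])

    chunks = []
    for t in range(0, dataset.n_frames, frame_stride):
        f_true = dataset.true_field(t)
        f_est = field_fn(t, rows) if model is not None else 0.0
        err = f_true - f_est
        mask = dataset.frame_mask(t)
        chunks.append(np.hypot(err[0], err[1])[mask].astype(np.float32))
    pooled = np.concatenate(chunks)
    if pooled.size == 0:
        raise ValueError("empty mask union: no pixels to pool")
    return pooled_stats(pooled)
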