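"""Dataset, model and image I/O.

Images and fields travel as NIfTI (2D grids stored as degenerate 3D
volumes; vector fields with the component on the last axis), surrogate
series and acquisition specs as CSV, experiment configuration as YAML.

A dataset directory written by :func:`save_dataset` contains::

    frames.nii       (T, m, nx) stack of partial-data frames
    specs.csv        per-frame acquisition spec + time
    surrogate.csv    time, s_1[, d_1, phase]
    truth/           optional: I_true, parameter maps, masks

Frame order is recovered from the ``frame`` column of specs.csv, not from
file names.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .correspondence import CorrespondenceModel, SurrogateSeries

__all__ = [
    "save_image", "load_image", "save_surrogate_csv", "load_surrogate_csv",
    "save_dataset", "load_dataset", "save_model", "load_model",
]


def save_image(path, data, spacing=(1.0, 1.0)):
    data = np.asarray(data, dtype=np.float64)
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data.T)[..., None], affine), str(path))


def load_image(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.squeeze(arr).T


def save_stack(path, stack):
    """Save a (T, m, nx) frame stack (or (N, 2, ny, nx) coefficients)."""
    arr = np.asarray(stack, dtype=np.float64)
    nib.save(nib.Nifti1Image(arr.T, np.eye(4)), str(path))


def load_stack(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float).T


def save_surrogate_csv(path, series: SurrogateSeries):
    cols = {"time": series.times}
    for j in range(series.values.shape[1]):
        cols[f"s_{j + 1}"] = series.values[:, j]
        if series.derivative is not None:
            cols[f"d_{j + 1}"] = series.derivative[:, j]
    if series.phase is not None:
        cols["phase"] = series.phase
    pd.DataFrame(cols).to_csv(path, index=False)


def load_surrogate_csv(path) -> SurrogateSeries:
    df = pd.read_csv(path)
    s_cols = sorted(c for c in df.columns if c.startswith("s_"))
    d_cols = sorted(c for c in df.columns if c.startswith("d_"))
    return SurrogateSeries(
        times=df["time"].to_numpy(),
        values=df[s_cols].to_numpy(),
        derivative=df[d_cols].to_numpy() if d_cols else None,
        phase=df["phase"].to_numpy() if "phase" in df.columns else None,
    )


def save_dataset(directory, frames, specs, surrogate: SurrogateSeries, truth: dict | None = None):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_stack(d / "frames.nii", np.stack([np.asarray(f) for f in frames]))
    rows = []
    for i, s in enumerate(specs):
        rows.append({
            "frame": i, "mode": s.mode, "row_start": s.row_start, "n_rows": s.n_rows,
            "profile_sigma": "" if s.profile_sigma is None else s.profile_sigma,
            "time": s.time,
        })
    pd.DataFrame(rows).to_csv(d / "specs.csv", index=False)
    save_surrogate_csv(d / "surrogate.csv", surrogate)
    if truth:
        td = d / "truth"
        td.mkdir(exist_ok=True)
        for name, arr in truth.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                save_image(td / f"{name}.nii", arr)
            else:
                save_stack(td / f"{name}.nii", arr)


def load_dataset(directory):
    """Load a dataset directory -> (frames, specs, surrogate, truth).

    Frames are ordered by the ``frame`` index recorded in specs.csv; a
    missing file or a surrogate shorter than the frame count raises an
    error naming the first missing frame.
    """
    d = Path(directory)
    for required in ("frames.nii", "specs.csv", "surrogate.csv"):
        if not (d / required).exists():
            raise FileNotFoundError(f"dataset is missing {required}")
    stack = load_stack(d / "frames.nii")
    df = pd.read_csv(d / "specs.csv").sort_values("frame")
    if len(df) != stack.shape[0]:
        raise ValueError(f"specs.csv lists {len(df)} frames but frames.nii holds {stack.shape[0]}")
    specs = []
    frames = []
    for _, row in df.iterrows():
        sigma = row["profile_sigma"]
        sigma = None if (isinstance(sigma, str) and sigma == "") or pd.isna(sigma) else float(sigma)
        specs.append(AcquisitionSpec(mode=row["mode"], row_start=int(row["row_start"]),
                                     n_rows=int(row["n_rows"]), profile_sigma=sigma,
                                     time=float(row["time"])))
        frames.append(stack[int(row["frame"])])
    surrogate = load_surrogate_csv(d / "surrogate.csv")
    if len(surrogate) < len(frames):
        raise ValueError(
            f"surrogate.csv has {len(surrogate)} samples; no sample for frame {len(surrogate)}"
        )
    truth = {}
    td = d / "truth"
    if td.exists():
        for p in sorted(td.glob("*.nii")):
            arr = np.asarray(nib.load(str(p)).dataobj, dtype=float).T
            truth[p.stem] = arr[0] if arr.ndim == 3 and arr.shape[0] == 1 else arr
    return frames, specs, surrogate, truth


def load_landmarks(path) -> np.ndarray:
    """Read a plain-text landmark list (one ``row col`` pair per line,
    whitespace separated, as distributed with public lung-CT landmark
    sets); extra columns beyond the first two are ignored."""
    pts = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) >= 2:
            pts.append([float(parts[0]), float(parts[1])])
    if not pts:
        raise ValueError(f"no landmarks found in {path}")
    return np.asarray(pts)


def save_model(path_prefix, model: CorrespondenceModel):
    """Serialize a model as a NIfTI coefficient stack plus a JSON sidecar."""
    prefix = Path(path_prefix)
    save_stack(prefix.with_suffix(".nii"), model.coefficients)
    sidecar = {
        "kind": model.kind,
        "n_terms": model.n_terms,
        "cpg_spacing": model.cpg_spacing,
        "image_shape": None if model.image_shape is None else list(model.image_shape),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path_prefix) -> CorrespondenceModel:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    coef = load_stack(prefix.with_suffix(".nii"))
    shape = meta["image_shape"]
    return CorrespondenceModel(kind=meta["kind"], coefficients=coef,
                               cpg_spacing=meta["cpg_spacing"],
                               image_shape=None if shape is None else tuple(shape))
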