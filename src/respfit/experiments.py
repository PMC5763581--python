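"""Canonical phantom replication experiments.

One runner per acquisition regime, each mirroring the corresponding
simulation-study protocol end to end: generate the calibrated phantom
dataset, fit the correspondence model (directly against a given reference,
or inside the alternating MCIR scheme), and evaluate displacement-field
error and - where a reconstruction is produced - agreement with the true
image.

The runners are the single source of truth for the study conditions
(model kind, control-point spacing, calibration target, reference mode per
regime) and are shared by the command-line ``run`` command, the test
suite, and ``scripts/acceptance.py``.
"""
from __future__ import annotations

from .evaluation import image_agreement, model_dfe
from .fitting import FitConfig, SurrogateMotionModel
from .mcir import fit_with_mcir, mcir_average
from .phantom import PhantomSpec, simulate_dataset

__all__ = ["run_regime_experiment", "run_experiment", "REGIME_DEFAULTS"]

#: Study conditions per regime: model kind, CPG spacing (px), reference
#: mode, and the no-motion mean-DFE calibration target (px).
REGIME_DEFAULTS = {
    "full": dict(kind="periodic_bspline", n_terms=8, cpg_spacing=5.0, reference="given",
                 dfe_target=3.56, levels=3, max_iter=50),
    "slab": dict(kind="linear_sdot", cpg_spacing=5.0, reference="given",
                 dfe_target=3.53, levels=3, max_iter=50),
    "thin_slice": dict(kind="linear_sdot", cpg_spacing=10.0, reference="mcir-average",
                       dfe_target=5.98, levels=3, max_iter=50, n_outer=10),
    "thick_slice": dict(kind="linear_sdot", cpg_spacing=5.0, reference="mcir-superres",
                        dfe_target=2.98, levels=3, max_iter=50, n_outer=9),
}


def run_regime_experiment(regime: str, seed: int = 0, overrides: dict | None = None) -> dict:
    """Run one canonical phantom experiment and return its metrics.

    The returned dict contains the dataset conditions, the pooled DFE
    statistics with no motion and with the fitted model, and (for MCIR
    regimes) reconstruction-vs-truth agreement for both the fitted model
    and a no-motion reconstruction.
    """
    params = dict(REGIME_DEFAULTS[regime])
    params.update(overrides or {})
    ds = simulate_dataset(PhantomSpec(regime=regime, seed=seed,
                                      dfe_target=params["dfe_target"]))
    cfg = FitConfig(cpg_spacing=params["cpg_spacing"], levels=params["levels"],
                    max_iterations=params["max_iter"])
    out = {
        "regime": regime,
        "seed": seed,
        "n_frames": ds.n_frames,
        "size": ds.spec.size,
        "conditions": {k: v for k, v in params.items() if k != "reference"},
    }

    eval_stride = 1
    if params["reference"] == "given":
        est = SurrogateMotionModel(
            kind=params["kind"], cpg_spacing=params["cpg_spacing"],
            levels=params["levels"], max_iter=params["max_iter"],
            n_terms=params.get("n_terms"),
        )
        est.fit(ds.frames, ds.surrogate, specs=ds.specs, reference=ds.I_true)
        model = est.model_
        out["final_cost"] = est.final_cost_
    else:
        method = "superres" if params["reference"] == "mcir-superres" else "average"
        model, recon, trace = fit_with_mcir(
            ds.frames, ds.specs, ds.surrogate, kind=params["kind"], config=cfg,
            method=method, n_outer=params.get("n_outer", 3),
            n_terms=params.get("n_terms"),
        )
        out["round_costs"] = trace
        m, s, p, r = image_agreement(recon, ds.I_true, ds.body_mask)
        out[f"recon_{method}_model"] = dict(abs_mean=m, abs_std=s, abs_p95=p, pearson_r=r)
        eval_stride = params.get("eval_stride", 1)

    nm_mean, nm_std, nm_p95 = model_dfe(ds, None, frame_stride=eval_stride)
    fm_mean, fm_std, fm_p95 = model_dfe(ds, model, frame_stride=eval_stride)
    out["dfe_no_motion"] = dict(mean=nm_mean, std=nm_std, p95=nm_p95)
    out["dfe_model"] = dict(mean=fm_mean, std=fm_std, p95=fm_p95)

    # averaging reconstruction under the fitted model (and without motion),
    # for the reconstruction-agreement comparison
    if regime in ("slab", "thin_slice", "thick_slice"):
        recon_avg, _ = mcir_average(ds.frames, ds.specs, model, ds.surrogate, ds.shape)
        m, s, p, r = image_agreement(recon_avg, ds.I_true, ds.body_mask)
        out["recon_average_model"] = dict(abs_mean=m, abs_std=s, abs_p95=p, pearson_r=r)
        recon_nm, _ = mcir_average(ds.frames, ds.specs, None, ds.surrogate, ds.shape)
        m, s, p, r = image_agreement(recon_nm, ds.I_true, ds.body_mask)
        out["recon_average_no_motion"] = dict(abs_mean=m, abs_std=s, abs_p95=p, pearson_r=r)

    out["_model"] = model
    out["_dataset"] = ds
    return out


def run_experiment(config: dict) -> dict:
    """Run an experiment described by a configuration mapping.

    Recognized keys: ``regime`` (required), ``seed``, and any override of
    the regime defaults (``kind``, ``cpg_spacing``, ``max_iter``,
    ``levels``, ``dfe_target``, ``reference``, ``n_outer``).  If
    ``out_dir`` is set, the metrics, the fitted model and any
    reconstruction are written there.
    """
    config = dict(config)
    regime = config.pop("regime")
    seed = int(config.pop("seed", 0))
    out_dir = config.pop("out_dir", None)
    result = run_regime_experiment(regime, seed=seed, overrides=config)
    if out_dir is not None:
        _write_results(out_dir, result)
    return result


def _write_results(out_dir, result: dict):
    import json
    from pathlib import Path

    import pandas as pd

    from .io import save_model

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    model = result.pop("_model")
    result.pop("_dataset")
    save_model(d / "model", model)
    rows = []
    for key in ("dfe_no_motion", "dfe_model"):
        rows.append({"metric": key, **result[key]})
    for key in [k for k in result if k.startswith("recon_")]:
        rows.append({"metric": key, **result[key]})
    pd.DataFrame(rows).to_csv(d / "metrics.csv", index=False)
    (d / "summary.json").write_text(json.dumps(
        {k: v for k, v in result.items() if not k.startswith("_")}, indent=1, default=float))
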