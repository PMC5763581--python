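# respfit

Surrogate-driven respiratory motion models fitted **directly** to dynamic
image data — full frames or *partial* data (slabs of slices, single thin
slices, thick slices with a Gaussian profile) — with motion-compensated
image reconstruction (MCIR) built in.

## The problem

Breathing moves the anatomy of the thorax and abdomen during imaging and
treatment. A *correspondence model* predicts the internal motion from easily
measured respiratory surrogate signals `S_t` (breathing belt, spirometry,
skin displacement, respiratory phase):

```
M_t = Σₙ Rₙ φₙ(S_t)
```

where `M_t` are the control-point displacements of a cubic B-spline
free-form deformation and `φ` is a linear, polynomial or periodic-B-spline
basis in the signals. Classically one registers every dynamic image first
and regresses the transformations against the signals — impossible when a
single frame (one slice of a helical CT, one thick MR slice) cannot drive a
registration on its own. respfit instead optimizes the model coefficients
`R` on **all frames at once**, minimizing

```
C_total = Σ_t ‖ P_t − A_t( T(I₀, M_t) ) ‖²
```

with `T` the B-spline warp of the reference image and `A_t` the frame's
acquisition operator (row sampling, Gaussian slice profile). The gradient
flows through the exact adjoints `A*_t` (back-embedding) and `T*`
(push-interpolation), so any partial-data geometry with a computable
adjoint plugs in. When no reference image exists, reconstruction and
fitting alternate: MCIR by weighted averaging or super-resolution
iterative back-projection produces `I₀`, the model is refitted, and so on —
both the motion and a motion-free image come out of the partial data alone.

The package ships a seeded 2D lung-like phantom generator that animates a
known linear correspondence model under four acquisition regimes (10 full
frames / 187 slabs / 3010 thin rows in alternating sweeps / 1500
overlapping thick rows), which is how everything here is validated:
displacement-field error (DFE) against the known truth, and reconstruction
agreement against the true image.

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from respfit import PhantomSpec, simulate_dataset, SurrogateMotionModel, model_dfe

# 10 noisy full frames of a 128-px phantom, one idealized breathing cycle,
# calibrated so the mean no-motion displacement error is 3.56 px
ds = simulate_dataset(PhantomSpec(regime="full", seed=1, dfe_target=3.56))

est = SurrogateMotionModel(kind="periodic_bspline", n_terms=8,
                           cpg_spacing=5.0, levels=3, max_iter=50)
est.fit(ds.frames, ds.surrogate, specs=ds.specs, reference=ds.I_true)

print("no motion:", np.round(model_dfe(ds, None), 2))
print("fitted   :", np.round(model_dfe(ds, est.model_), 2))
```

prints

```
no motion: [ 3.56  3.5  10.86]
fitted   : [0.34 0.37 1.  ]
```

(mean, standard deviation and 95th percentile of the pooled per-pixel
displacement-field error, in pixels): the fitted phase model reduces the
mean motion error from 3.56 px to about a third of a pixel. For partial
data without a reference image, use the alternating estimator instead:

```python
from respfit import MotionCompensatedReconstructor
rec = MotionCompensatedReconstructor(kind="linear_sdot", cpg_spacing=5.0,
                                     method="superres", n_outer=10, max_iter=50)
rec.fit(ds.frames, ds.surrogate, specs=ds.specs)
rec.model_   # fitted correspondence model
rec.image_   # motion-compensated reconstruction
```

A thin CLI covers the same workflows:

```
respfit simulate --regime slab --seed 1 --out data/slab
respfit fit --data data/slab --ref data/slab/truth/I_true.nii --model linear_sdot --out model
respfit fit-mcir --data data/slab --method average --out out/
respfit evaluate --data data/slab --model model
respfit run --config config.yaml
```

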