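# Methods

## The model

respfit estimates surrogate-driven respiratory motion models directly from
dynamic image data.  A correspondence model maps one or more respiratory
surrogate signals `S_t` (e.g. a breathing-belt trace and its temporal
derivative, or a respiratory phase) to the motion parameters of a spatial
transformation:

    M_t = sum_{n=1..N_r} R_n * phi_n(S_t)

The motion parameters are the control-point displacements of a cubic
B-spline free-form deformation (spacing the same in both directions, the
lattice covering the image plus one support margin; control point `j` of an
axis sits at pixel `(j-1)*spacing`).  The basis `phi` defines the model
family:

| kind                  | phi(S_t)                  | captures                      |
|-----------------------|---------------------------|-------------------------------|
| `linear_sdot`         | `[s, s_dot, 1]`           | intra- + inter-cycle variation|
| `linear_sdot_no_offset` | `[s, s_dot]`            | same, reference at mean pos.  |
| `poly2`               | `[s^2, s, 1]`             | curvilinear s-dependence      |
| `periodic_bspline`    | periodic cubic B-splines in phase | intra-cycle only      |
| `constant`            | `[1]`                     | one static transform          |

Instead of registering each frame and regressing the results, the
coefficients `R` are optimized on all frames at once: the total cost is the
summed SSD between each measured frame `P_t` (full image, slab of rows, a
single thin row, or a thick row with a Gaussian slice profile) and data
simulated from the reference image,

    C_total = sum_t || P_t - A_t( T(I_0, M_t) ) ||^2,

where `T` warps the reference by bilinear pull-interpolation and `A_t` is
the frame's acquisition operator.  The gradient with respect to `R` follows
the chain rule through exact adjoints: SSD gradient -> `A*_t` (embedding /
profile convolution transpose) -> multiplication by the sampled derivative
of the bilinear interpolant -> B-spline transpose onto the lattice ->
scaling by `phi_n`.  Every link is the exact derivative of the discrete
forward computation, so the analytic gradient agrees with finite
differences of the cost itself, and every forward/adjoint pair passes a
dot-product identity test at machine precision.  No regularization or
constraint term is used; the lattice spacing is the only smoothness
control.

Minimization uses scipy's Polak-Ribiere nonlinear conjugate gradient with
Wolfe line search inside a coarse-to-fine image pyramid (downsampling by 2
per level; partial-data frames are smoothed/decimated along their axes and
their row positions mapped to the coarse grid; the control-point spacing in
pixels is kept constant, so it doubles physically at each coarser level).
Stopping is at `tol` times the initial gradient infinity-norm (default
1e-3) or `max_iterations` per level.

### The periodic basis

The periodic model with `N_r` control points on the phase circle uses the
standard periodized uniform cubic B-spline: with `N*theta = k + j`, control
point `n` (1-indexed) carries segment polynomial `B_m(j)`,
`m = ((n-k-2) mod N) + 1`, zero when `m > 4`.  The segment index must
*decrease* as the interval `k` advances - that is what makes each basis
function a continuous shifted bump (`B_m(1) = B_{m-1}(0)`); the sign is
easy to get wrong, and the discontinuous variant is useless (it cannot even
represent a smooth periodic signal).  The basis is non-negative and sums to
one at every phase, and `phi(0) = [0, 1/6, 4/6, 1/6]` for `N_r = 4`.

For replicating the one-cycle cos^4 protocol we default to `N_r = 8`
control points: the sampled motion contains the first two harmonics of the
cycle (cos^4 = 3/8 + cos/2 + cos2/8, and its derivative weights the second
harmonic up), and a uniform cubic spline needs roughly four knots per
period of the finest oscillation present to represent it accurately.  With
`N_r = 4` the quadrature component of the second harmonic is outside the
representable span entirely, which puts a representation floor on the
achievable error comparable to the entire error budget of the
replication.  `n_terms` is configurable.

## Partial data and acquisition operators

`AcquisitionSpec` describes how each frame samples the image: `full`,
`slab`/`slice` (contiguous rows), or `thick_slice` (Gaussian slice profile
along rows, truncated at +-3 sigma and renormalized, then row sampling).
Internally each operator is a small dense matrix acting on a band of rows,
so the adjoint is the exact matrix transpose; boundaries are zero-padded to
keep the operator linear.  The profile convolution represents the
*resolution difference* between the reference image and the dynamic data:
it is applied when the reference is finer than the data (a truth image or a
super-resolution reconstruction) and omitted when the reference is an
averaging reconstruction at the data's own through-slice resolution -
applying it then would double-blur the simulation, and the fit responds
with spurious "deblurring" deformations of several pixels.

## Motion-compensated reconstruction

*Averaging*: each frame is embedded with `A*_t` and carried into the
reference space by push-interpolation (splatting - the adjoint of the
warp, avoiding transform inversion) together with its occupancy weights;
the reconstruction is accumulated intensity over accumulated weight.
Pixels receiving no weight (holes) are re-filled by re-embedding at doubled
row density; only hole pixels take the refined values.  At native
resolution none of the four phantom regimes produces holes.

*Super-resolution*: iterative back-projection initialized with the
averaging reconstruction; each iteration simulates all frames from the
current estimate, back-projects the residuals through the exact adjoints
(the acquisition Gaussian doubles as the back-projection kernel) and adds
the weight-normalized correction.  On the thick-slice phantom under the
true model, agreement with the true image peaks after a few iterations
and then degrades slowly as noise is amplified, even though the data
residual keeps shrinking; the default is therefore 5 iterations, with an
early stop after three consecutive residual increases.

## Alternating estimation (no reference image)

When no reference exists, `fit_with_mcir` alternates reconstruction and
fitting, starting from a no-motion reconstruction.  Two details decide
whether this converges, and both were found the hard way:

1. **Fresh multi-resolution fits each round.**  Warm-starting from the
   previous round's coefficients freezes the iteration at a
   self-consistent pair (a ~20% amplitude-shrunk model and the matching
   slightly blurred reconstruction reproduce the data almost as well as
   the truth).  A cold pyramid fit re-estimates the gross motion at coarse
   levels, where the reconstruction's residual blur is irrelevant.
2. **Gauge fixing.**  The distribution of a breathing signal is skewed
   (long dwell near exhale), so a motion-blurred reconstruction's
   structures concentrate at the dwell position rather than the mean.  A
   model without a constant term cannot represent that static shift and
   tilts its surrogate slopes instead (amplitude shrinkage); a model with
   a free constant term recovers the slopes exactly but drags a static
   error of several pixels into the next reconstruction.  The scheme
   therefore fits *with* the constant term and then projects the
   time-mean motion out of the model (zeroing the constant term; for the
   periodic model, subtracting the mean from every control point, which
   is exact by the partition of unity) before reconstructing.  With
   mean-zero surrogates the reconstruction is defined to sit at the
   average anatomical position, so the static component is pure gauge.

With both in place the alternation contracts geometrically toward the
jointly data-consistent solution (the thin- and thick-slice replication
experiments exercise it end to end).  Alternation stops when the total
cost no longer decreases (beyond a 1% tolerance - the cost is measured
against a reference that changes every round) or after `n_outer` rounds.

## The phantom generator

`respfit.phantom` simulates the study conditions end to end.  The 2D
lung-like image (body ellipse of soft tissue, two low-intensity lungs, 45
seeded vessel-like blobs, a tumour-like disc, smooth soft-tissue
structures, maximum intensity exactly 1500) is animated by a dense linear
correspondence model `field = r1*s + r2*s_dot` with smooth random
parameter maps (Gaussian-smoothed noise at a scale of one-sixth of the
image, weighted up inside the lungs, tapering to zero at the body
boundary).  The derivative-channel maps are scaled so the hysteresis
displacement has 0.4 times the standard deviation of the value-channel
displacement - mild, plausible loop width.  Soft-tissue structure matters:
a featureless body makes motion unobservable to any intensity-based method
and the whole exercise ill-posed.

Surrogates: an idealized single cos^4 cycle (with phase t/N attached) for
the full-image regime, and a quasiperiodic generator (per-cycle amplitude
+-20% and period +-15% jitter around a 4 s breathing period) standing in
for the real breathing traces of the other regimes.  Signals are
normalized to mean zero; derivatives are finite differences of the
samples, so the generating model is *exactly* representable by the fitted
one.

The four regimes: 10 full 128 px frames over one cycle; 187 slabs
(17 positions x 8 rows x 11 times, 0.4 s apart) at 136 px; 3010 single
rows in 10 alternating-direction sweeps (5 s per sweep) at 301 px with
doubled motion amplitude; and 1500 thick rows at 150 px (5 acquisitions
with 1-px offsets, each sweeping a 30-slice stack of 5-px-FWHM Gaussian
slices ten times at 0.2 s per slice).  Gaussian noise with sigma = 3% of
the maximum intensity (45) is added to the simulated frames only.  All
randomness derives from a single seed; identical specs give identical
datasets.

Motion amplitude can be calibrated so the pooled mean no-motion
displacement-field error (mean true displacement magnitude inside the
deformed phantom) matches a requested value; two fixed-point rounds land
within a few percent.  The canonical experiments calibrate to the
respective baselines (3.56 / 3.53 / 5.98 / 2.98 px).

What the generator does *not* emulate: sliding motion between lungs and
chest wall (so nothing here validates sliding handling), 3D geometry,
anatomy-dependent noise, surrogate measurement error, or imperfect
surrogate-motion correlation - the generating model is exactly of the
fitted family, so passing recovery tests demonstrate correctness of the
estimation machinery, not robustness to model misspecification.

## Evaluation

Displacement-field error (DFE) is the per-pixel Euclidean distance between
true and estimated fields, pooled over every pixel inside the deformed
phantom over all time-points (mean, SD, 95th percentile; percentiles use
linear interpolation between order statistics).  Reconstructions are
compared with the true image by absolute intensity differences and the
Pearson correlation over the body mask.  Landmark errors use the
snap-to-voxel convention: propagate, round to the nearest voxel centre,
and measure in millimetres (by default the target landmark is snapped
too; both conventions are offered).

## Problem sizes and defaults

The canonical experiment runners (`respfit.experiments`) fit with
control-point spacings of 5 px (full, slab, thick) and 10 px (thin), a
3-level pyramid, 50 CG iterations per level, and 9-10 alternation rounds
for the MCIR regimes.  The iteration budget doubles as the noise
regularizer: with no constraint term, iterating much further keeps
lowering the SSD below the noise floor while the displacement error
deteriorates.  These sizes run the whole replication suite on a single
CPU in tens of minutes; all of them are exposed as parameters.

## Known limitations

* Transformations are plain B-spline FFDs: no sliding-interface or
  diffeomorphic parameterization, no folding control.
* SSD is the only similarity measure, so all data must be intra-modality.
* The acquisition operators cover row-wise sampling and Gaussian slice
  profiles; projection and k-space operators are out of scope.
* The alternating scheme's gauge fixing assumes mean-zero surrogates; with
  non-centred signals the reconstruction's position is undefined by the
  data alone.
* 2D only.
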