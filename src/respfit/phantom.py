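"""Synthetic 2D lung-like phantom with surrogate-driven ground-truth motion.

The generator produces a smooth "lung-like" 2D image (body ellipse of
soft-tissue intensity, two low-intensity lungs containing bright
vessel-like blobs and a tumour-like disc, maximum intensity 1500) and
animates it with dense displacement fields drawn from a *linear*
correspondence model on a surrogate signal and its temporal derivative:

    field_t(x) = r1(x) * s_t + r2(x) * sdot_t        (per component, pixels)

The four per-pixel parameter maps (x/y components of r1 and r2) are
band-limited random fields, smooth at a configurable length scale, larger
inside the lungs and tapering to zero at the body boundary.  Because the
generating model is linear in the surrogate, the ground-truth fields
satisfy it exactly, which the recovery tests exploit.

Four acquisition regimes mirror common dynamic protocols (sizes in
pixels, frame counts fixed by the regime):

=============  =====  =========================================================
regime         size   frames
=============  =====  =========================================================
full            128   10 full noisy frames over one idealized cos^4 cycle
slab            136   17 positions x 8 contiguous rows x 11 times = 187 slabs
thin_slice      301   10 alternating-direction sweeps of single rows = 3010 rows
thick_slice     150   150 overlapping thick rows, 5-pixel Gaussian slice profile
=============  =====  =========================================================

Gaussian noise with standard deviation ``noise_sigma_fraction`` of the
maximum intensity (default 3% of 1500 = 45) is added to the simulated
frames only - never to the fields or the surrogate.  All randomness flows
from the spec seed, so identical specs give identical datasets.

The motion amplitude can be calibrated so that the pooled mean no-motion
displacement-field error (the mean true displacement magnitude inside the
deformed phantom) hits a requested target, which is how the replication
experiments match their printed baselines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import FWHM_TO_SIGMA, AcquisitionSpec
from .correspondence import SurrogateSeries, normalize_surrogate, temporal_derivative
from .transform import warp_pull

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "make_phantom",
    "make_parameter_maps",
    "make_surrogate",
    "simulate_dataset",
    "REGIME_SIZES",
]

REGIME_SIZES = {"full": 128, "slab": 136, "thin_slice": 301, "thick_slice": 150}

SOFT_TISSUE = 1000.0
LUNG = 150.0
TUMOUR = 1200.0


def _ellipse_mask(size, cy, cx, ry, rx):
    y, x = np.mgrid[0:size, 0:size] / (size - 1.0)
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def phantom_masks(size: int):
    """Deterministic body and lung support masks (proportions fixed)."""
    body = _ellipse_mask(size, 0.52, 0.50, 0.44, 0.46)
    lung_l = _ellipse_mask(size, 0.45, 0.32, 0.27, 0.17)
    lung_r = _ellipse_mask(size, 0.45, 0.68, 0.27, 0.17)
    return body, lung_l | lung_r


def make_phantom(size: int, seed: int = 0, return_masks: bool = False):
    """The lung-like 2D phantom image, deterministic for a given seed.

    Intensities: air 0 outside the body, soft tissue inside, low-intensity
    lungs with seeded bright vessel-like blobs and a tumour-like disc.
    The image is lightly smoothed and rescaled so its maximum is exactly
    1500.
    """
    if size < 64:
        raise ValueError("phantom size must be at least 64 pixels")
    rng = np.random.default_rng(seed)
    body, lungs = phantom_masks(size)
    img = np.zeros((size, size))
    img[body] = SOFT_TISSUE
    img[lungs] = LUNG

    y, x = np.mgrid[0:size, 0:size]
    # soft-tissue structure (muscle/fat/organ-like): without intensity
    # variation throughout the body, motion there would be unobservable by
    # any intensity-based method and the simulated study would be ill-posed
    soft = body & ~lungs
    soft_idx = np.argwhere(soft)
    for _ in range(10):
        cy, cx = soft_idx[rng.integers(len(soft_idx))]
        sig = size * rng.uniform(0.04, 0.10)
        amp = rng.uniform(-0.25, 0.25) * SOFT_TISSUE
        img += amp * np.exp(-0.5 * (((y - cy) ** 2 + (x - cx) ** 2) / sig**2)) * soft
    for _ in range(25):
        cy, cx = soft_idx[rng.integers(len(soft_idx))]
        sig = size * rng.uniform(0.015, 0.035)
        amp = rng.uniform(-0.15, 0.15) * SOFT_TISSUE
        img += amp * np.exp(-0.5 * (((y - cy) ** 2 + (x - cx) ** 2) / sig**2)) * soft

    # vessel-like blobs throughout the lungs (lungs are densely vascularized)
    lung_idx = np.argwhere(lungs)
    for _ in range(45):
        cy, cx = lung_idx[rng.integers(len(lung_idx))]
        sig = size * rng.uniform(0.005, 0.015)
        peak = rng.uniform(400.0, 1400.0)
        img += peak * np.exp(-0.5 * (((y - cy) ** 2 + (x - cx) ** 2) / sig**2)) * lungs

    # tumour-like disc in the right lung
    disc = _ellipse_mask(size, 0.55, 0.70, 0.05, 0.05)
    img[disc] = TUMOUR

    img = ndimage.gaussian_filter(img, max(0.008 * size, 0.8))
    img = np.clip(img, 0.0, None)
    img *= 1500.0 / img.max()
    if return_masks:
        return img, body, lungs
    return img


def make_parameter_maps(size: int, smoothness: float, amplitude: float, seed: int = 0):
    """Four smooth per-pixel model-parameter maps (r_x1, r_x2, r_y1, r_y2).

    Gaussian-smoothed white noise, normalized to unit standard deviation
    over the body, clipped at 3 sigma, scaled by ``amplitude`` (pixels per
    surrogate unit), weighted up inside the lungs and tapered to zero at
    the body boundary so the phantom edge barely moves.
    """
    rng = np.random.default_rng(seed)
    body, lungs = phantom_masks(size)
    # taper: normalized distance-to-boundary ramp inside the body
    dist = ndimage.distance_transform_edt(body)
    taper = np.minimum(dist / (0.15 * size), 1.0)
    lung_w = ndimage.gaussian_filter(lungs.astype(float), 0.08 * size)
    lung_w /= max(lung_w.max(), 1e-12)
    weight = taper * (0.35 + 0.65 * lung_w)

    maps = []
    for _ in range(4):
        f = ndimage.gaussian_filter(rng.standard_normal((size, size)), smoothness)
        f /= max(f[body].std(), 1e-12)
        f = np.clip(f, -3.0, 3.0)
        maps.append(amplitude * weight * f)
    return tuple(maps)  # (r_x1, r_x2, r_y1, r_y2)


def make_surrogate(kind: str, n_frames: int | None = None, seed: int = 0,
                   times: np.ndarray | None = None, period: float = 4.0,
                   amp_jitter: float = 0.2, period_jitter: float = 0.15,
                   normalize: bool = True) -> SurrogateSeries:
    """Generate a surrogate signal series.

    ``cos4``
        One idealized respiratory cycle: s(t) = cos^4(pi t / N) sampled at
        the N frame times, with the respiratory phase theta = t/N attached.
    ``quasiperiodic``
        A free-breathing-like trace: consecutive cos^4 cycles whose
        amplitude (+-``amp_jitter``) and period (+-``period_jitter``,
        fractions of the base ``period``) vary per cycle, sampled at the
        supplied acquisition ``times``.

    The returned series is mean-zero (unless ``normalize=False``) with the
    temporal derivative filled by finite differences of the samples.
    """
    if kind == "cos4":
        if n_frames is None:
            raise ValueError("cos4 needs n_frames")
        t = np.arange(n_frames, dtype=float)
        raw = np.cos(np.pi * t / n_frames) ** 4
        series = SurrogateSeries(times=t, values=raw, phase=t / n_frames)
    elif kind == "quasiperiodic":
        if times is None:
            raise ValueError("quasiperiodic needs acquisition times")
        times = np.asarray(times, dtype=float)
        rng = np.random.default_rng(seed)
        starts = [times[0]]
        periods = []
        amps = []
        while starts[-1] <= times[-1]:
            periods.append(period * (1.0 + period_jitter * rng.uniform(-1, 1)))
            amps.append(1.0 + amp_jitter * rng.uniform(-1, 1))
            starts.append(starts[-1] + periods[-1])
        raw = np.empty_like(times)
        cyc = np.searchsorted(np.asarray(starts), times, side="right") - 1
        for i, t in enumerate(times):
            c = cyc[i]
            raw[i] = amps[c] * np.cos(np.pi * (t - starts[c]) / periods[c]) ** 4
        series = SurrogateSeries(times=times, values=raw)
    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")
    series = temporal_derivative(series)
    if normalize:
        series = normalize_surrogate(series)
    return series


@dataclass
class PhantomSpec:
    """Study conditions of one simulated dataset."""

    regime: str = "full"
    size: int | None = None
    noise_sigma_fraction: float = 0.03
    max_intensity: float = 1500.0
    smoothness: float | None = None  # parameter-map smoothing scale, pixels
    amplitude: float = 1.0  # motion amplitude scale (pixels per surrogate unit)
    hysteresis: float = 0.4  # derivative-channel displacement std relative to value channel
    dfe_target: float | None = None  # calibrate mean no-motion DFE to this many pixels
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIME_SIZES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.size is None:
            self.size = REGIME_SIZES[self.regime]
        if self.smoothness is None:
            self.smoothness = self.size / 6.0
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise_sigma_fraction must be >= 0")
        if self.regime == "thin_slice" and self.dfe_target is None and self.amplitude == 1.0:
            # thin-slice data represent higher-resolution anatomy: motion is
            # twice as large in pixels
            self.amplitude = 2.0


@dataclass
class PhantomDataset:
    """A simulated dataset plus its ground truth."""

    spec: PhantomSpec
    I_true: np.ndarray
    body_mask: np.ndarray
    lung_mask: np.ndarray
    r1: np.ndarray  # (2, ny, nx): value-channel maps (r_y1, r_x1)
    r2: np.ndarray  # (2, ny, nx): derivative-channel maps (r_y2, r_x2)
    surrogate: SurrogateSeries
    specs: list
    frames: list

    @property
    def n_frames(self) -> int:
        return len(self.specs)

    @property
    def shape(self):
        return self.I_true.shape

    def true_field(self, t: int) -> np.ndarray:
        """Dense ground-truth displacement field of frame t, shape (2, ny, nx)."""
        s = self.surrogate.values[t, 0]
        sd = self.surrogate.derivative[t, 0]
        return self.r1 * s + self.r2 * sd

    def true_fields(self):
        """Iterate over the per-frame ground-truth fields (kept lazy: the
        thin-slice regime has 3010 frames)."""
        for t in range(self.n_frames):
            yield self.true_field(t)

    def frame_mask(self, t: int) -> np.ndarray:
        """Support of the deformed phantom at frame t (pixels with image data)."""
        warped = warp_pull(self.body_mask.astype(float), self.true_field(t), pad=0.0)
        return warped > 0.5


def _regime_protocol(regime: str, size: int):
    """Frame times and acquisition specs of the canonical protocols."""
    specs = []
    if regime == "full":
        for t in range(10):
            specs.append(AcquisitionSpec("full", time=float(t)))
    elif regime == "slab":
        dt = 0.4  # 11 samples cover ~1.1 breath cycles of period 4 s
        n_pos, n_rows, n_times = 17, 8, 11
        assert n_pos * n_rows == size
        k = 0
        for p in range(n_pos):
            for _ in range(n_times):
                specs.append(AcquisitionSpec("slab", row_start=p * n_rows, n_rows=n_rows,
                                             time=k * dt))
                k += 1
    elif regime == "thin_slice":
        dt = 5.0 / size  # a 5 s sweep over all rows
        k = 0
        for sweep in range(10):
            rows = range(size) if sweep % 2 == 0 else range(size - 1, -1, -1)
            for r in rows:
                specs.append(AcquisitionSpec("slice", row_start=r, n_rows=1, time=k * dt))
                k += 1
    elif regime == "thick_slice":
        sigma = 5.0 / FWHM_TO_SIGMA  # slice thickness (FWHM) of 5 pixels
        dt = 0.2
        n_pos = size // 5
        n_rep = 10  # the slice stack is swept 10 times per acquisition, so
        # every position is imaged in 10 different breath cycles
        k = 0
        for a in range(5):  # 5 sequential acquisitions, 1-pixel offsets
            for _ in range(n_rep):
                for j in range(n_pos):
                    specs.append(AcquisitionSpec("thick_slice", row_start=a + 5 * j, n_rows=1,
                                                 profile_sigma=sigma, time=k * dt))
                    k += 1
    else:
        raise ValueError(regime)
    times = np.array([s.time for s in specs])
    return times, specs


def _mean_no_motion_dfe(ds_like, frame_stride: int = 1) -> float:
    """Pooled mean true-displacement magnitude inside the deformed phantom."""
    total = 0.0
    count = 0
    for t in range(0, ds_like.n_frames, frame_stride):
        f = ds_like.true_field(t)
        mask = ds_like.frame_mask(t)
        if mask.any():
            total += np.hypot(f[0], f[1])[mask].sum()
            count += int(mask.sum())
    if count == 0:
        raise ValueError("empty mask union")
    return total / count


def simulate_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Generate a complete simulated dataset for one acquisition regime.

    Per frame: the phantom is deformed by the ground-truth field, the
    acquisition operator extracts the frame's partial data, and Gaussian
    noise is added.  If ``spec.dfe_target`` is set, the parameter maps are
    first rescaled (two fixed-point rounds) so the pooled mean no-motion
    DFE lands within a few percent of the target.
    """
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(spec.seed).spawn(4)]
    size = spec.size
    I_true, body, lungs = make_phantom(size, seed=seeds[0], return_masks=True)

    times, aspecs = _regime_protocol(spec.regime, size)
    if spec.regime == "full":
        surrogate = make_surrogate("cos4", n_frames=len(aspecs))
    else:
        surrogate = make_surrogate("quasiperiodic", times=times, seed=seeds[1])

    rx1, rx2, ry1, ry2 = make_parameter_maps(size, spec.smoothness, spec.amplitude,
                                             seed=seeds[2])
    r1 = np.stack([ry1, rx1])
    r2 = np.stack([ry2, rx2])
    # balance the hysteresis channel: its displacement std is `hysteresis`
    # times the value channel's, regardless of the signal's time scale
    s = surrogate.values[:, 0]
    sd = surrogate.derivative[:, 0]
    r2 *= spec.hysteresis * s.std() / max(sd.std(), 1e-12)

    ds = PhantomDataset(spec=spec, I_true=I_true, body_mask=body, lung_mask=lungs,
                        r1=r1, r2=r2, surrogate=surrogate, specs=aspecs, frames=[])

    if spec.dfe_target is not None:
        stride = 10 if spec.regime == "thin_slice" else 1
        for _ in range(2):
            current = _mean_no_motion_dfe(ds, frame_stride=stride)
            scale = spec.dfe_target / max(current, 1e-12)
            ds.r1 = ds.r1 * scale
            ds.r2 = ds.r2 * scale

    rng = np.random.default_rng(seeds[3])
    sigma = spec.noise_sigma_fraction * spec.max_intensity
    for t, aspec in enumerate(aspecs):
        band, S = aspec.operator(size)
        f = ds.true_field(t)
        warped = warp_pull(I_true, f[:, band, :], rows=band, pad=0.0)
        P = S @ warped
        if sigma > 0:
            P = P + rng.normal(0.0, sigma, size=P.shape)
        ds.frames.append(P)
    return ds
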