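# Methods

## The imaging model

A thin holographic diffuser placed a few millimetres in front of a bare
sensor, with an aperture against it, maps a temporally incoherent point
source to a high-contrast pseudorandom pattern confined to a rectangular
support on the sensor. Dividing the source's beam into `n = n_u x n_v`
thin sub-beams partitions that support into non-overlapping *sub-images*,
one per sub-beam, each statistically distinct because it samples a
different patch of the random surface. Radiance is parameterized on two
parallel planes: the light field is `l(s, t, u, v)` with `(s, t)` on the
spatial sampling plane and `(u, v)` on the angular (diffuser) plane.

Because intensities of incoherent rays add, a single point's pattern is
`f_i = H_i g_i`, where the columns of `H_i` are its n placed sub-images
and `g_i` its per-ray radiances, and a multi-point scene gives

    d = T l,      T = (H_1, H_2, ..., H_k),

a single 2-D image that linearly encodes the 4-D light field. `T` has more
columns than rows — the decoding can exceed the pixel count of the sensor
— so inversion needs priors:

    argmin_{l >= 0}  1/2 ||d - T l||_2^2 + tau ||Psi l||_1,

with `Psi` the identity (point-like scenes) or a first-order
finite-difference operator (extended objects).

Lateral shift invariance makes calibration single-shot: every `H_i` is the
on-axis `H_0` with its support translated by the point's pixel offset, so
segmenting one captured pattern determines `T` completely. The same
structure turns `T l` into n 2-D convolutions (one per angular sample),
which is how the production forward/adjoint path is implemented; an
explicit sparse `T` is materialized only at small scale, as a brute-force
oracle the convolution path is tested against (agreement to ~1e-15
relative; truncation at the sensor border is implemented identically in
both paths so the equivalence is exact).

## Conventions and key parameters

* Index order `(s, t, u, v)`, row-major, 0-based; `s`/`t` align with
  sensor rows/columns. Angular samples lie on a regular `n_u x n_v` grid
  over the square aperture, row-major; sub-image `(i, j)` of the even
  segmentation is bound to angular sample `(u=i, v=j)` by geometric
  position. Nothing downstream depends on which fixed order is chosen, only
  on calibration and reconstruction sharing it.
* Spatial sample `(s, t)` maps to the integer pixel shift
  `((s - n_s//2) * stride, (t - n_t//2) * stride)` with stride 1 px by
  default. Spatial-sampling sweeps refine the grid over a fixed field of
  view by shrinking the stride.
* Support detection threshold: 1% of the peak intensity. The intensity
  outside the aperture-limited support is treated as negligible; with the
  synthetic generator it is exactly zero.
* If the detected support is not divisible by `(n_u, n_v)` it is
  symmetrically zero-padded to the next multiple (trimming would discard
  encoded rays), nudged inward if a sensor border is hit.
* Refocusing is parameterized by the dimensionless slope `beta` (spatial
  samples per angular index); `beta_to_depth` converts to metric depth
  given the plane separation and pitch ratio, since the geometry-to-depth
  calibration is scene-specific. Interpolation is bilinear with zero
  outside the field of view.
* `ReconSettings` defaults: `tau = 1e-3 * max|T' d|` (data-scaled; the
  sparsity weight is otherwise scene-dependent), step = `1/L` with `L`
  from deterministic power iteration on `T'T`, 200 iterations, stopping on
  relative objective change below 1e-6. All-zero initialization; the
  solver path contains no randomness.

## The solver

Monotone FISTA (accelerated proximal gradient with a safeguard that never
accepts an objective increase). Non-negativity is folded into the
proximal step: for `Psi = I` the prox is the one-sided soft threshold
`max(x - tau*step, 0)`; for the finite-difference `Psi` the prox is an
anisotropic-TV-with-positivity problem solved by ~30 inner fast
gradient-projection iterations on the dual (step 1/8, the operator-norm
bound of the 2-D difference operator). Convergence is judged on accepted
steps only — a rejected momentum step repeats the previous objective
value, which says nothing about stationarity. On small instances the
returned objective is verified to land within 1% of a 50,000-iteration
projected-gradient reference computed with the explicit dense matrix.

## What the synthetic generator emulates — and what it does not

Sub-images are smoothed (Gaussian, `correlation_px` ~ 1-2 px), clipped,
contrast-normalized white noise on a rectangular support: independent
across tiles, strictly positive inside the support at the default contrast
0.9, zero outside. This reproduces the statistical structure the
transmission model actually uses — distinguishable, non-overlapping,
shift-invariant sub-images — and nothing more. Real caustic patterns have
correlated ray structure across sub-image boundaries, partial sub-image
overlap, shot/read noise, and a depth-dependent magnification that is only
approximately uniform; none of these are modelled (wave-optical rendering
is explicitly out of scope). Passing tests therefore demonstrate
correctness of the calibration/encoding/decoding machinery under the
model's own assumptions, not end-to-end performance on laboratory data.
Depth variation is emulated through the scaling property of thin
scatterers: the pattern of a point at a different depth is the base
pattern rescaled about its support centre (bilinear; the physical scale
lives in metadata, not in resampling).

Hardware-scale defaults mirror a 2048x2048 sensor with 6.5 µm pixels, a
~6x6 mm² aperture and a 10 mm diffuser-sensor gap; tests and examples run
at reduced geometry (sensors of 64-256 px, supports of 16-192 px) chosen
so every experiment, including the dense-SVD conditioning sweeps and the
multi-point recovery, completes in seconds to a few minutes on one CPU.

## Experiment designs used by the acceptance suite

* **Multi-point recovery.** Twelve unit-weight points with
  minimum Chebyshev separation 5 on a 64x64x4x4 grid (160 px sensor,
  64 px support), depth slopes cycling {0, +2, -2} so every per-angle
  offset is integral. The solver runs 800 iterations — the iteration
  budget is a convergence control sized to the problem, with the stopping
  tolerance unchanged. Recovery is scored by refocused-slice peak
  positions (within one sample), whole-array correlation (>= 0.9), and
  per-point in-focus slope.
* **Hourglass.** A slightly blurred (sigma 0.7 samples) synthetic point at
  slope 1 on a 5x5 angular grid; FWHM of the through-peak profile over a
  beta sweep must be unimodal with the waist at the true slope.
* **Angular-sampling trend.** The measured image is the pattern of a point
  at a *different depth* (base pattern rescaled by 4/3), reconstructed
  with kernels segmented from the same base pattern at 2x2, 4x4 and 6x6.
  A sub-beam's calibrated sub-image tracks the depth-induced local
  displacement only up to its own extent, so the residual per-channel blur
  is the in-tile stretch `(scale-1) * tile`, which shrinks as angular
  sampling grows: resolved FWHM (through the in-focus refocused slice,
  integrated cross-sections) must fall monotonically. Geometry (support
  144 px, tiles 72/36/24, scale 4/3) is chosen so the in-focus shifts are
  exactly integral at all three samplings, keeping interpolation blur out
  of the comparison, and the texture correlation length is 1 px so even
  the 24 px tiles remain strongly distinguishable. A same-depth noiseless
  point would be recovered exactly at every sampling and show no trend.
* **Conditioning.** `T_sub` for 5 collinear points spaced by 4 sample gaps
  (distributed-points surrogate, a scaled-down analog of widely spaced
  sources) versus 20 grid-adjacent points (area surrogate), swept over
  spatial samplings {24, 48} at fixed 48 px field of view (stride 2 and
  1 px) and angular samplings {2, 4, 6}, five seeds, majority scoring.
  Support 96 px keeps the smallest tiles at 16 px, well above the texture
  correlation length; with 8 px tiles the small-tile correlation artifacts
  reverse the angular-sampling trend, which is why the analysis is
  specified at tiles >= 16 px. "Weak angular dependence" is asserted as a
  below-5x spread of condition numbers across angular samplings at fixed
  spatial sampling, a bound frozen from pilot runs (observed spreads are
  ~2-3x).

## Numerical notes and limitations

* FFT-based convolution is used throughout; against the explicit matrix it
  agrees to ~1e-15 relative, far inside the 1e-10 contract.
* FWHM is the linear-interpolated width between the outermost half-peak
  crossings and is reported in spatial-sample units; the physical size
  additionally depends on the sample pitch, and published resolved sizes
  without units are interpreted the same way.
* Depth maps use variance-of-Laplacian focus scoring (window 9 by
  default); ties break toward the smallest slope so output is
  deterministic.
* The condition number is reported as infinity only for an exactly zero
  minimum singular value; near-singular submatrices report their (large)
  finite ratio.
* Fully off-sensor spatial samples produce zero transmission-matrix
  columns (with a warning); partially off-sensor contributions are
  truncated at the border, which is the physical sensor behaviour.
* The solver is a single-CPU dense/FFT implementation; the full
  2048x2048x6x6 problem runs only through the convolution path and is not
  exercised by the routine test suite.
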