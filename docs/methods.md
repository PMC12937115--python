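# Methods

## Model

`velspec` models velocity spectrum imaging: Fourier encoding of the
per-voxel distribution of convective water velocities using
velocity-selective preparation pulses. The physical chain is

1. **Preparation train** (`physics`, `blochsim`): a 90y excitation, four
   rectangular gradient blips interleaved with three 180x refocusing
   pulses, and a tip-up pulse. RF pulses are ideal instantaneous rotations
   (adiabatic waveform internals are not modelled); gradient lobes are
   rectangles on a uniform sample grid with a fixed 0.5 ms gap to the
   adjacent RF events. The *effective* gradient — sign-flipped after each
   refocusing pulse — has zero net area (position-independence) and first
   moment m1, so a spin at constant velocity v accrues phase γ·m1·v.
   Constant velocity during the ~45 ms train is assumed; acceleration and
   diffusion during the train are out of scope, though the diffusion
   weighting the blips unavoidably impose is reported as a b-value
   (γ²∫[∫G_eff]², typically ~10 s/mm², under the few-tens bound relevant
   for these preparations).
2. **Encoding** (`encode`): tip-up about y leaves Mz = cos(γ m1 v), about
   x leaves sin(γ m1 v); a cos/sin image pair is one complex sample
   S(m1) = Σ_v ρ(v)·exp(iγ m1 v) of velocity k-space. The integral is
   discretized as a bin-center sum on the phantom's velocity axis; the
   phantom module is the single source of binning. All voxels share
   M0 = 1 (no proton-density or relaxation weighting).
3. **Decoding** (`recon`): the stages a scanner series goes through, in
   fixed order, each toggleable — rephase by the zero-encode reference,
   combine pairs, Savitzky–Golay smooth (off by default; window 7, order
   3 when on — the values are conventional choices, not claims), cubic
   detrend (on by default), conjugate completion for half ladders,
   raised-cosine window, per-voxel DFT magnitude, unit-sum
   normalization, optional global-mean-spectrum regression.

## Sampling relations and the bin-width convention

For a uniform ladder of N moments with step Δm1 the decoded axis has
N bins, alias period W = 2π/(γ·Δm1), bin width ΔV = W/N and unaliased
half-width v_max = W/2 = π/(γ·Δm1). Two textbook-style statements follow:
v_max is set by the moment *step*, ΔV by the moment *extent*. For an
even-N full ladder the extent relation takes the familiar form
ΔV = π/(γ·m1_max) exactly (m1_max = (N/2)·Δm1). For a conjugate-completed
half ladder (N = 2n−1 odd, m1_max = (n−1)·Δm1) that form would differ
from the DFT-dual width by a factor (2n−2)/(2n−1) ≈ 1.7% at n = 31; the
package uses the DFT-dual width ΔV = 2π/(γ·N·Δm1) throughout, because it
is the convention under which the decode is the exact inverse of the
encode and the aliasing arithmetic is exact. Under it, 31 half-Fourier
encode pairs spanning a ±2.6 cm/s spectrum give 61 bins of 0.0852 cm/s —
consistent with both printed protocol numbers at their stated precision.

Even-length axes carry their extra bin on the positive side (centers
k·ΔV, k = −(n/2−1)..n/2), the only convention consistent with the 30-bin
phantom axis running −8.06..+8.64 cm/s. Because the absolute moment per
unit gradient amplitude depends on blip timings that are not part of the
protocol description, ladders are parameterized directly by ΔV or v_max
(`ladder_for_axis`) rather than by gradient amplitude.

## Phantoms (what the synthetic data emulates)

The generator reproduces the two laboratory phantoms used to validate the
method, rendered on a default 48³ grid of 2 mm voxels with tubes along z:

- **Multitube**: eight parallel tubes, diameters equally spaced
  2.25–4.0 mm, inside a spherical stationary-water chamber. One shared
  pressure drop makes Poiseuille peak velocity ∝ d²; the scale is
  anchored so the largest tube's mean is 7.24 cm/s (its measured value),
  giving 2.29 cm/s for the smallest. On the −8.06..+8.64 cm/s axis the
  four fastest tubes' laminar support exceeds the axis edge and aliases —
  deliberately retained, as the aliasing behavior is part of what the
  phantom demonstrates.
- **Loop**: two limbs of a 12.7 mm tube with equal and opposite flow
  (default ±1 cm/s mean, chosen so the laminar support stays inside the
  ±2.6 cm/s axis) in a stationary bath.

Laminar velocity densities come in two forms, selectable per run: the
skewed-parabola profile ρ(v) ∝ √(1 − v/Vmax) and the spin-count
(uniform-area) Poiseuille density, constant on [0, Vmax]. Only the
uniform model has mean exactly Vmax/2, consistent with the Poiseuille
identity v_max_tube = 2·v_mean, so end-to-end mean-velocity checks use
it; the published description of the profile shape is ambiguous between
the two, which is why both are exposed rather than one guessed.
Densities are bin-*integrated* (exact CDF differences per bin, with mass
beyond ±v_max wrapped into its alias bin) rather than point-sampled, so
voxel densities sum to 1 exactly and the stored truth is exactly what a
finite moment ladder can represent. Tube walls get partial-volume
mixtures from 4× in-plane supersampling. The corruption model adds a
static smooth background phase field, a slow polynomial gain drift
across frames (order ≤ 3) and additive complex Gaussian noise whose
`noise_sd` is the per-component standard deviation, all reproducible
from one seed.

What the synthetic data does *not* emulate: cardiac pulsatility and bulk
motion, eddy currents and B0/B1 imperfections, the spiral readout and
image reconstruction stage, coil sensitivities, relaxation contrast, or
diffusion attenuation. Passing tests therefore show the encoding/decoding
mathematics and pipeline mechanics are correct under the stated
measurement model — not that the method is robust to every in vivo
confound.

## Numerical choices

- Internal units are SI (T/m, s, m/s, rad); G/cm and cm/s are converted
  at interfaces. γ = 2.6752218744e8 rad/s/T.
- Gradient waveforms integrate on midpoint samples, exact for rectangular
  lobes; `build_train` solves the blip amplitude from the exact discrete
  lobe centers so the achieved m1 matches the target to machine
  precision, and raises a named infeasibility error when the requested
  moment does not fit between the RF pulses at the amplitude cap.
- Bloch evolution applies exact axis-angle rotations and analytic
  per-segment phase accrual — no small-step integration — so
  Bloch-vs-analytic agreement is at rounding level (~1e-14), not a
  convergence tolerance.
- The decode uses the explicit conjugate-kernel matrix with 1/N
  normalization; it is the exact inverse of the encode for any N
  consecutive integer moment indices (symmetric or one-sided-extra),
  which keeps the asymmetric phantom ladder exactly invertible.
- Detrending projects real and imaginary parts onto a degree-3 polynomial
  basis over the moment index; fitting magnitudes would break Fourier
  linearity. A constant (stationary water) series detrends to zero —
  eliminating the zero-velocity peak is an inherent property of the
  stage, demonstrated in the tests.
- The raised-cosine window is 0.5·(1 + cos(πk/k_max)) over signed moment
  index: exactly 1 at the zero encode and 0 at the extreme moment.
- Rephasing masks voxels whose zero-encode magnitude is below 5% of the
  series maximum; normalization masks zero-sum voxels and counts them in
  the log. Global-mean regression floors negative residuals at zero to
  preserve fraction semantics and keeps the raw residual for diagnostics.
- Savitzky–Golay smoothing uses `scipy.signal.savgol_filter` with
  polynomial edge interpolation, so polynomials up to the filter order
  pass unchanged everywhere.
- Non-uniform moment ladders are rejected rather than silently regridded.

## Design decisions that were genuinely open

- **Where smoothing and global regression act**: SG smoothing is applied
  to the combined complex series before detrending; global-mean
  regression acts on the normalized spectrum image. Both insertion points
  are config-switchable since the protocol description leaves them
  ambiguous.
- **Half-ladder bin width**: DFT-dual convention, as argued above.
- **Monte-Carlo vs quadrature voxel integration** (`simulate_voxel`):
  the default integrates the Bloch response with one isochromat per
  velocity bin weighted by the bin fraction (deterministic, matches the
  analytic model to ~1e-12); a multinomial mode draws isochromats at
  random for statistical validation, with accuracy ~1/√n (≈0.02 at
  n = 2000).
- **Problem sizes**: tests and the acceptance script run the full 48³
  grids and 201-velocity Bloch sweeps of the study conditions; only
  pipeline-mechanics unit tests use smaller slabs, since the per-voxel
  operations are position-independent.

## Known limitations

- Single-axis encoding only; the three-axis laboratory-frame acquisition
  is three independent runs.
- The sphere/tube geometry is axis-aligned and z-uniform; no curved loop
  return path, no partial-volume blending at the sphere boundary (voxel
  centers decide membership there).
- The corruption model's drift multiplies all voxels equally; spatially
  varying drift (e.g. eddy-current-like spatial gradients across velocity
  bins) is not modelled.
- Relaxation during the preparation is available in the Bloch module but
  not propagated into the analytic encode, which assumes the theory's
  relaxation-free limit.
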