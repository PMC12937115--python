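# velspec

**Velocity spectrum imaging with velocity-selective preparation pulses — a
simulation and decoding toolkit.**

Water in living tissue moves convectively at very different speeds within a
single imaging voxel: capillary blood at ~0.1–0.2 cm/s, ventricular CSF below
~0.4 cm/s, perivascular (glymphatic) fluid far slower still. Conventional
phase-contrast MRI reports one mean velocity per voxel and cannot separate
these populations. Velocity spectrum imaging measures the *distribution*
ρ(v) — the fraction of a voxel's spins moving at each velocity along an
encoding axis — by Fourier-encoding velocity with velocity-selective
preparation pulses. `velspec` implements the physics, a Bloch-equation
validator, laminar flow phantoms, the analytic forward model with a
scanner-like corruption model, and the full decoding pipeline, so the
method's sampling relations, aliasing behavior and spectrum recovery are
reproducible without scanner data.

## The method

A preparation train (90y — gradient blips interleaved with three 180x
refocusing pulses — tip-up) leaves a moving spin with residual longitudinal
magnetization set by the phase it accrued, φ = γ·m1·v, where m1 is the first
moment of the effective gradient (sign-flipped at each refocusing pulse) and
the zeroth moment cancels. Tipping up about y or x gives the quadrature pair

    Mz_cos(v) = Mxy(v)·cos(γ m1 v),    Mz_sin(v) = Mxy(v)·sin(γ m1 v)

so one cos/sin image pair samples the Fourier transform of the voxel's
velocity density at "velocity k-space" position γ·m1:

    S(m1) = Σ_v ρ(v) · exp(i γ m1 v)

Stepping m1 through a uniform ladder of N values with step Δm1 samples N
points of velocity k-space; an inverse DFT recovers ρ(v) on N bins of width
ΔV = 2π/(γ·N·Δm1) with unaliased half-width v_max = π/(γ·Δm1). Because ρ(v)
is real, S(−m1) = conj(S(m1)), so only non-negative moments need be acquired
(half-Fourier): n encode pairs yield 2n−1 bins. Velocities beyond ±v_max
alias modulo the axis width 2·v_max.

The decoding pipeline mirrors scanner processing: per-voxel rephasing by the
zero-encode reference, cos/sin pair combination, optional Savitzky–Golay
smoothing and cubic detrending over the moment index, conjugate completion,
Hanning windowing, per-voxel DFT magnitude, unit-sum normalization, and
optional global-mean-spectrum regression.

## Worked example

Eight parallel tubes (2.25–4.0 mm) share one pressure drop, so laminar flow
gives mean velocities ∝ diameter², anchored at 7.24 cm/s for the largest
tube. Encode on a 30-step ladder spanning −8.06..+8.64 cm/s (0.576 cm/s
bins), add 1% complex noise, decode, and compare tube ROI spectra with the
windowed ground truth:

```sh
python examples/03_multitube_pipeline.py
```

```
tube table (equal pressure drop → v_mean ∝ d²):
  d=2.25 mm  v_mean= 2.29 cm/s  v_max= 4.58 cm/s
  ...
  d=4.00 mm  v_mean= 7.24 cm/s  v_max=14.48 cm/s  (aliases)

per-tube ROI recovery (central 3 slices, windowed truth):
  d=2.25 mm  corr=0.9999  negative-bin mass=0.148
  ...
  d=4.00 mm  corr=0.9984  negative-bin mass=0.392
```

Correlations ≥ 0.998 show the decoded spectra match the laminar truth; the
fastest tube's 39% negative-bin mass is the aliased tail of a velocity
distribution that extends past the +8.64 cm/s axis edge, exactly as sampling
theory predicts. `examples/04_loop_direction.py` shows the complementary
result: two loop limbs at ±1 cm/s decoded from half-sampled data keep 97% of
their spectral mass on their own flow sign. Other examples cover the
sampling-relation arithmetic (31 half-Fourier encodes → 61 bins at
0.085 cm/s over ±2.6 cm/s) and the Bloch-vs-analytic response equivalence;
`examples/05_cli_workflow.sh` runs the same pipeline through the `velspec`
command-line interface on NIfTI files.

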