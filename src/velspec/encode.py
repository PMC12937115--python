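"""Analytic forward model: voxel velocity densities → encoded image series.

Each preparation with first moment m1 leaves residual longitudinal
magnetization Σ_v ρ(v)·cos(γ·m1·v) (cos variant) or Σ_v ρ(v)·sin(γ·m1·v)
(sin variant); acquired together they sample the discrete Fourier
transform of the voxel's velocity density at "velocity k-space" position
γ·m1. The series is stored complex so the synthetic path and an acquired
scanner series share one data model; a clean encode has zero imaginary
part, and scanner-like corruption (static background phase, slow
multiplicative drift across encodes, complex Gaussian noise) is applied by
`corrupt`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import GAMMA
from .phantom import PhantomImage
from .physics import MomentLadder, velocity_axis


@dataclass
class EncodedSeries:
    """4D complex series, one cos + one sin frame per ladder moment.

    frames has shape (nz, ny, nx, 2·n_moments), interleaved cos-then-sin
    per moment in ascending-moment order; frame_manifest lists
    (m1 T·s²/m, "cos"|"sin") per frame.
    """

    frames: np.ndarray
    frame_manifest: list[tuple[float, str]]
    ladder: MomentLadder
    provenance: str = "clean"
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        if self.frames.shape[-1] != 2 * len(self.ladder):
            raise ValueError("frame count must be 2 × ladder length")
        if self.frames.shape[-1] != len(self.frame_manifest):
            raise ValueError("manifest length must match frame count")

    @property
    def n_moments(self) -> int:
        return len(self.ladder)

    def frame_index(self, m1: float, variant: str) -> int:
        for i, (m, var) in enumerate(self.frame_manifest):
            if var == variant and abs(m - m1) <= 1e-15 + 1e-9 * abs(m1):
                return i
        raise KeyError(f"no {variant} frame at m1={m1}")

    @property
    def zero_cos_index(self) -> int:
        return self.frame_index(0.0, "cos")


@dataclass(frozen=True)
class CorruptionSpec:
    """Reproducible measurement-corruption model.

    noise_sd is the per-component standard deviation of the additive
    complex Gaussian noise, as a fraction of M0. drift_coeffs are
    polynomial coefficients over normalized frame index (order ≤ 3),
    multiplying the signal as (1 + drift). background_phase is either a
    scalar amplitude (rad) of a smooth random low-frequency phase field,
    or an explicit (nz, ny, nx) field in rad.
    """

    noise_sd: float = 0.0
    drift_coeffs: tuple = ()
    background_phase: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.drift_coeffs) > 4:
            raise ValueError("drift polynomial order is limited to 3")


def forward_encode(phantom: PhantomImage, ladder: MomentLadder) -> EncodedSeries:
    """Encode a phantom's densities into a clean cos/sin series."""
    axis = velocity_axis(ladder)
    if axis.n_bins != phantom.axis.n_bins or not np.allclose(
        axis.centers, phantom.axis.centers, rtol=1e-9, atol=1e-12
    ):
        raise ValueError("phantom velocity axis inconsistent with ladder")
    v = phantom.axis.centers * 0.01  # m/s
    m1 = ladder.m1_values
    phases = GAMMA * np.outer(m1, v)  # (n_moments, n_bins)
    cos_k = phantom.densities @ np.cos(phases).T  # (z,y,x,n_moments)
    sin_k = phantom.densities @ np.sin(phases).T
    nz, ny, nx = phantom.shape
    frames = np.empty((nz, ny, nx, 2 * len(ladder)), dtype=complex)
    frames[..., 0::2] = cos_k
    frames[..., 1::2] = sin_k
    manifest = []
    for m in m1:
        manifest.append((float(m), "cos"))
        manifest.append((float(m), "sin"))
    return EncodedSeries(
        frames=frames,
        frame_manifest=manifest,
        ladder=ladder,
        provenance="clean",
        voxel_size_mm=phantom.voxel_size_mm,
    )


def smooth_phase_field(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Random smooth phase field: sum of low-frequency separable cosines."""
    nz, ny, nx = shape
    coords = [np.linspace(0, 1, n) for n in (nz, ny, nx)]
    field = np.zeros(shape)
    for _ in range(4):
        freq = rng.uniform(0.2, 1.0, size=3)
        ph = rng.uniform(0, 2 * np.pi, size=3)
        w = rng.normal()
        field += w * (
            np.cos(2 * np.pi * freq[0] * coords[0] + ph[0])[:, None, None]
            * np.cos(2 * np.pi * freq[1] * coords[1] + ph[1])[None, :, None]
            * np.cos(2 * np.pi * freq[2] * coords[2] + ph[2])[None, None, :]
        )
    peak = np.max(np.abs(field))
    if peak > 0:
        field *= amplitude / peak
    return field


def corrupt(series: EncodedSeries, spec: CorruptionSpec) -> EncodedSeries:
    """Apply background phase, frame drift and complex noise (seeded)."""
    if series.provenance != "clean":
        raise ValueError("corrupt expects a clean series")
    rng = np.random.default_rng(spec.seed)
    frames = series.frames.copy()
    shape = frames.shape[:3]
    n_frames = frames.shape[-1]

    if isinstance(spec.background_phase, np.ndarray):
        phase = spec.background_phase
        if phase.shape != shape:
            raise ValueError("explicit phase field shape mismatch")
    elif spec.background_phase != 0.0:
        phase = smooth_phase_field(shape, float(spec.background_phase), rng)
    else:
        phase = None
    if phase is not None:
        frames = frames * np.exp(1j * phase)[..., None]

    if spec.drift_coeffs:
        xk = np.arange(n_frames) / max(n_frames - 1, 1)
        drift = np.zeros(n_frames)
        for p, c in enumerate(spec.drift_coeffs):
            drift += c * xk**p
        frames = frames * (1.0 + drift)

    if spec.noise_sd > 0:
        noise = rng.normal(scale=spec.noise_sd, size=frames.shape + (2,))
        frames = frames + noise[..., 0] + 1j * noise[..., 1]

    return replace(series, frames=frames, provenance="corrupted")
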