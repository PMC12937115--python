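"""Decoding pipeline: encoded image series → normalized velocity spectra.

The stages mirror how a scanner series is processed: (1) rephase every
frame at each voxel by the conjugate phase of the zero-encoded reference
frame, (2) combine cos/sin pairs into one complex sample per moment,
(3) optionally Savitzky–Golay smooth and polynomial-detrend the series
over the moment index (detrending removes the slowly varying component —
including the stationary-water plateau, which is why the zero-velocity
peak disappears after this stage), (4) conjugate-complete half-sampled
ladders using S(−m) = conj(S(m)) for real-valued spectra, (5) apply a
raised-cosine (Hanning) window against truncation ringing, (6) Fourier
transform over the moment dimension and take the magnitude, and
(7) normalize each voxel's spectrum to unit sum, optionally followed by
global-mean-spectrum regression to suppress shared drift structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .constants import GAMMA
from .encode import EncodedSeries
from .phantom import DensityVector
from .physics import LadderScheme, MomentLadder, VelocityAxis, completed_ladder, velocity_axis

logger = logging.getLogger(__name__)


@dataclass
class VelocityKSpaceSeries:
    """Per-voxel complex samples of velocity k-space, ordered by moment."""

    values: np.ndarray  # (nz, ny, nx, n_moments) complex
    ladder: MomentLadder

    def __post_init__(self):
        if self.values.shape[-1] != len(self.ladder):
            raise ValueError("series length must equal ladder length")


@dataclass
class SpectrumImage:
    """Per-voxel magnitude velocity spectrum on a velocity axis."""

    spectra: np.ndarray  # (nz, ny, nx, n_bins), non-negative
    axis: VelocityAxis
    normalized: bool = False
    mask: np.ndarray | None = None
    residual_raw: np.ndarray | None = None  # unfloored regression residual

    def __post_init__(self):
        if self.spectra.shape[-1] != self.axis.n_bins:
            raise ValueError("spectra bins must match axis")


def rephase(
    series: EncodedSeries, threshold: float = 0.05
) -> tuple[EncodedSeries, np.ndarray]:
    """Remove per-voxel static phase using the zero-encode cos frame.

    Every frame is multiplied by the unit-modulus conjugate phase of the
    reference; the reference becomes real non-negative. Voxels whose
    reference magnitude falls below threshold × series maximum are masked
    out (their phase is meaningless noise).
    """
    ref = series.frames[..., series.zero_cos_index]
    mag = np.abs(ref)
    mask = mag > threshold * mag.max()
    unit = np.ones_like(ref)
    unit[mask] = ref[mask] / mag[mask]
    frames = series.frames * np.conj(unit)[..., None]
    frames[~mask] = 0.0
    return replace(series, frames=frames), mask


def combine_pairs(series: EncodedSeries) -> VelocityKSpaceSeries:
    """cos + i·sin per moment: one complex velocity-k-space sample each.

    The imaginary parts of the rephased frames are discarded (they carry
    only noise once the static phase is removed); the zero-moment sin
    frame, identically zero in theory, is ignored here by construction.
    """
    m1 = series.ladder.m1_values
    nz, ny, nx = series.frames.shape[:3]
    values = np.empty((nz, ny, nx, len(m1)), dtype=complex)
    for k, m in enumerate(m1):
        ic = series.frame_index(float(m), "cos")
        try:
            isn = series.frame_index(float(m), "sin")
        except KeyError as exc:
            raise ValueError(f"missing sin frame for moment {m}") from exc
        values[..., k] = series.frames[..., ic].real + 1j * series.frames[..., isn].real
    return VelocityKSpaceSeries(values=values, ladder=series.ladder)


def detrend(series: VelocityKSpaceSeries, order: int = 3) -> VelocityKSpaceSeries:
    """Subtract a least-squares polynomial over moment index per voxel.

    Real and imaginary parts are fitted independently (fitting magnitude
    would break Fourier linearity). A constant series detrends to zero —
    the mechanism that removes the stationary-water zero-velocity peak.
    """
    n = series.values.shape[-1]
    if n <= order + 1:
        raise ValueError("series too short for the requested polynomial order")
    x = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.polynomial.polyvander(x, order)  # (n, order+1)
    # Orthogonal projection onto the polynomial space: P = V (VᵀV)⁻¹ Vᵀ.
    proj = V @ np.linalg.solve(V.T @ V, V.T)
    resid = series.values - series.values @ proj.T
    return replace(series, values=resid)


def sg_smooth(
    series: VelocityKSpaceSeries, window_len: int = 7, polyorder: int = 3
) -> VelocityKSpaceSeries:
    """Savitzky–Golay smoothing along the moment dimension per voxel."""
    if window_len == 1:
        return series
    if window_len % 2 == 0 or window_len <= polyorder:
        raise ValueError("window_len must be odd and exceed polyorder")
    vals = series.values
    sm = savgol_filter(vals.real, window_len, polyorder, axis=-1, mode="interp") + 1j * savgol_filter(
        vals.imag, window_len, polyorder, axis=-1, mode="interp"
    )
    return replace(series, values=sm)


def conjugate_complete(series: VelocityKSpaceSeries) -> VelocityKSpaceSeries:
    """Fill negative moments by conjugate symmetry, S(−m) = conj(S(m)).

    Valid because a real-valued velocity spectrum has a Hermitian Fourier
    transform; this is what lets half of velocity k-space go unacquired.
    """
    lad = series.ladder
    if lad.scheme is not LadderScheme.half or np.any(lad.m1_values < 0):
        raise ValueError("conjugate completion requires a half-sampled ladder")
    n = len(lad)
    if n == 1:
        return series
    full_lad = completed_ladder(lad)
    nz, ny, nx = series.values.shape[:3]
    values = np.empty((nz, ny, nx, 2 * n - 1), dtype=complex)
    values[..., n - 1 :] = series.values
    values[..., : n - 1] = np.conj(series.values[..., :0:-1])
    return VelocityKSpaceSeries(values=values, ladder=full_lad)


def window_weights(ladder: MomentLadder, kind: str = "hanning") -> np.ndarray:
    """Raised-cosine taper over moments: 1 at m=0, →0 at the extremes."""
    if kind == "none":
        return np.ones(len(ladder))
    if kind != "hanning":
        raise ValueError(f"unknown window kind {kind!r}")
    k = ladder.indices
    k_max = np.max(np.abs(k))
    return 0.5 * (1.0 + np.cos(np.pi * k / k_max))


def apply_window(series: VelocityKSpaceSeries, kind: str = "hanning") -> VelocityKSpaceSeries:
    if kind == "none":
        return series
    w = window_weights(series.ladder, kind)
    return replace(series, values=series.values * w)


def decode_spectrum(series: VelocityKSpaceSeries) -> SpectrumImage:
    """Per-voxel DFT over moments; magnitude on the dual velocity axis.

    With N uniform moments m_k = k·Δm1 and bins v_j = j·ΔV satisfying
    γ·Δm1·ΔV = 2π/N, the decode matrix (1/N)·exp(−iγ m_k v_j) is the exact
    inverse of the encoding sum for densities supported on the bins —
    aliasing velocities modulo N·ΔV.
    """
    lad = series.ladder
    if lad.scheme is LadderScheme.half:
        raise ValueError("decode requires a full (completed) ladder")
    axis = velocity_axis(lad)
    v = axis.centers * 0.01
    E = np.exp(-1j * GAMMA * np.outer(lad.m1_values, v))  # (N, n_bins)
    spec = np.abs(series.values @ E) / len(lad)
    return SpectrumImage(spectra=spec, axis=axis, normalized=False)


def normalize_spectrum(image: SpectrumImage, mask: np.ndarray | None = None) -> SpectrumImage:
    """Scale each in-mask voxel's spectrum to unit sum (spin fractions)."""
    sums = image.spectra.sum(axis=-1)
    if mask is None:
        mask = sums > 0
    else:
        mask = mask.astype(bool)
    zero_sum = mask & (sums <= 0)
    n_zero = int(zero_sum.sum())
    if n_zero:
        logger.warning("%d in-mask voxels had zero spectral sum; masked out", n_zero)
    good = mask & (sums > 0)
    spectra = np.zeros_like(image.spectra)
    spectra[good] = image.spectra[good] / sums[good, None]
    return replace(image, spectra=spectra, normalized=True, mask=good)


def global_mean_regress(image: SpectrumImage, mask: np.ndarray | None = None) -> SpectrumImage:
    """Remove the global mean spectrum from each voxel by OLS over bins.

    The spatial mean spectrum over the mask acts as a regressor (plus an
    intercept); the per-voxel residual suppresses structure shared by all
    voxels — drift and the dominant stationary peak. Residuals are floored
    at zero to preserve fraction semantics; the raw residual is retained.
    """
    if mask is None:
        mask = image.mask
    if mask is None or not np.any(mask):
        raise ValueError("global regression needs a non-empty mask")
    gbar = image.spectra[mask].mean(axis=0)
    if np.std(gbar) == 0:
        raise ValueError("global mean spectrum has zero variance over bins")
    X = np.column_stack([np.ones_like(gbar), gbar])  # (n_bins, 2)
    proj = X @ np.linalg.solve(X.T @ X, X.T)
    resid = image.spectra - image.spectra @ proj.T
    resid[~mask] = 0.0
    return replace(
        image,
        spectra=np.clip(resid, 0.0, None),
        residual_raw=resid,
        normalized=False,
        mask=mask,
    )


@dataclass
class ReconConfig:
    """Stage toggles and parameters of the decoding pipeline.

    Defaults follow the phantom protocol: rephase, combine, cubic detrend,
    Hanning window, decode, normalize; Savitzky–Golay smoothing (window 7,
    order 3 — the human protocol) and global-mean regression are off.
    """

    rephase: bool = True
    mask_threshold: float = 0.05
    sg_window: int = 0  # 0 disables smoothing
    sg_order: int = 3
    detrend_order: int | None = 3  # None disables detrending
    window: str = "hanning"  # "hanning" | "none"
    normalize: bool = True
    global_regress: bool = False


def reconstruct(series: EncodedSeries, config: ReconConfig | None = None) -> SpectrumImage:
    """Run the full decoding pipeline on an encoded series."""
    config = config or ReconConfig()
    mask = None
    if config.rephase:
        series, mask = rephase(series, config.mask_threshold)
    vks = combine_pairs(series)
    if config.sg_window:
        vks = sg_smooth(vks, config.sg_window, config.sg_order)
    if config.detrend_order is not None:
        vks = detrend(vks, config.detrend_order)
    if vks.ladder.scheme is LadderScheme.half:
        vks = conjugate_complete(vks)
    vks = apply_window(vks, config.window)
    image = decode_spectrum(vks)
    image.mask = mask
    if config.normalize:
        image = normalize_spectrum(image, mask)
    if config.global_regress:
        image = global_mean_regress(image, image.mask)
    return image


def windowed_density(density: DensityVector, kind: str = "hanning") -> DensityVector:
    """Ground-truth density as seen through a windowed encode/decode.

    Encodes the density on the full ladder dual to its axis, applies the
    window, decodes and renormalizes — the reference a windowed
    reconstruction should be compared against (the window trades sidelobe
    ringing for main-lobe broadening).
    """
    axis = density.axis
    delta_m1 = 2 * np.pi / (GAMMA * axis.n_bins * axis.delta_v * 0.01)
    ladder = MomentLadder(
        m1_values=axis.indices * delta_m1,
        scheme=LadderScheme.full,
        zero_index=axis.zero_index,
        delta_m1=delta_m1,
        m1_max=float(np.max(np.abs(axis.indices)) * delta_m1),
    )
    v = axis.centers * 0.01
    E = np.exp(1j * GAMMA * np.outer(ladder.m1_values, v))
    S = E @ density.fractions
    S = S * window_weights(ladder, kind)
    rho = np.abs(np.conj(E.T) @ S) / axis.n_bins
    return DensityVector(axis=axis, fractions=rho / rho.sum())


def roi_spectrum(image: SpectrumImage, mask: np.ndarray) -> DensityVector:
    """Mean spectrum over an ROI, renormalized to unit sum."""
    mask = mask.astype(bool)
    if not np.any(mask):
        raise ValueError("empty ROI mask")
    mean = image.spectra[mask].mean(axis=0)
    s = mean.sum()
    if s <= 0:
        raise ValueError("ROI has zero total spectral mass")
    return DensityVector(axis=image.axis, fractions=mean / s)
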