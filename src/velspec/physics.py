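"""Gradient/RF timing model of the velocity-encoding preparation.

A velocity-selective preparation (90y — blip — 180x — blip — 180x — blip —
180x — blip — tip-up) imposes on each spin a phase proportional to its
velocity, φ = γ·m1·v, where m1 is the first moment of the *effective*
gradient (the physical waveform with its sign flipped after every
refocusing pulse). Sampling a ladder of first moments samples a "velocity
k-space"; its Fourier-dual grid of velocity-bin centers is the velocity
axis of the decoded spectrum.

Sampling relations (for a uniform ladder with step Δm1 completed to
N bins): the unaliased half-width is v_max = π/(γ·Δm1) and the bin width
is ΔV = 2π/(γ·N·Δm1), so the alias period is N·ΔV = 2·v_max. For an
even-n full ladder this is identical to ΔV = π/(γ·m1_max) with
m1_max = (n/2)·Δm1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .constants import GAMMA, si_to_cms


class TipAxis(str, Enum):
    """Axis of the final tip-up rotation.

    cos_variant: tip-up about y; residual Mz = Mxy·cos(γ·m1·v).
    sin_variant: tip-up about x; residual Mz = Mxy·sin(γ·m1·v).
    """

    cos_variant = "cos"
    sin_variant = "sin"


class LadderScheme(str, Enum):
    full = "full"
    half = "half"
    asymmetric = "asymmetric"


class InfeasibleTrainError(ValueError):
    """Requested first moment cannot be realized under the constraints."""


@dataclass(frozen=True)
class PulseTrain:
    """Timed RF events plus a uniformly sampled gradient waveform.

    rf_events are (time s, flip rad, axis label) tuples, strictly
    time-ordered within [0, duration]. Gradient samples are interpreted as
    piecewise-constant over [i·dt, (i+1)·dt); integrals use the midpoint
    times (i+0.5)·dt, which is exact for rectangular lobes.
    """

    rf_events: tuple
    tip_axis: TipAxis
    gradient: np.ndarray
    dt: float
    duration: float

    def __post_init__(self):
        g = np.asarray(self.gradient, dtype=float)
        if g.ndim != 1 or g.size == 0:
            raise ValueError("gradient must be a non-empty 1-D waveform")
        if not np.all(np.isfinite(g)):
            raise ValueError("gradient samples must be finite")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        times = [t for t, _, _ in self.rf_events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("rf_events must be strictly time-ordered")
        if times and (times[0] < 0 or times[-1] > self.duration + 1e-12):
            raise ValueError("rf_events must lie within [0, duration]")
        object.__setattr__(self, "gradient", g)

    @property
    def times(self) -> np.ndarray:
        """Midpoint sample times of the gradient waveform."""
        return (np.arange(self.gradient.size) + 0.5) * self.dt

    def refocusing_times(self) -> list[float]:
        return [t for t, flip, _ in self.rf_events if abs(abs(flip) - np.pi) < 1e-9]


@dataclass(frozen=True)
class Moments:
    """Effective gradient moments of a preparation train.

    kv = γ·m1 maps velocity to phase: φ = kv·v, rad per (m/s).
    """

    m0: float  # T·s/m
    m1: float  # T·s²/m
    kv: float  # rad/(m/s)


@dataclass(frozen=True)
class MomentLadder:
    """Uniformly spaced set of first moments ("velocity k-space" samples)."""

    m1_values: np.ndarray  # T·s²/m, ordered ascending
    scheme: LadderScheme
    zero_index: int
    delta_m1: float
    m1_max: float

    def __post_init__(self):
        v = np.asarray(self.m1_values, dtype=float)
        object.__setattr__(self, "m1_values", v)
        if v.size > 1:
            steps = np.diff(v)
            if not np.allclose(steps, self.delta_m1, rtol=1e-12, atol=1e-30):
                raise ValueError("ladder spacing is not uniform")
        if abs(v[self.zero_index]) > 1e-12 * max(self.m1_max, 1e-300):
            raise ValueError("zero_index does not point at the zero moment")

    def __len__(self) -> int:
        return self.m1_values.size

    @property
    def indices(self) -> np.ndarray:
        """Signed integer moment indices k with m1 = k·delta_m1."""
        return np.arange(len(self)) - self.zero_index


@dataclass(frozen=True)
class VelocityAxis:
    """Fourier-dual velocity grid of a moment ladder.

    centers/delta_v/v_max are in cm/s. v_max is the unaliased half-width:
    velocities are recovered modulo the alias period 2·v_max = n_bins·delta_v.
    """

    centers: np.ndarray  # cm/s
    delta_v: float  # cm/s
    v_max: float  # cm/s
    n_bins: int

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.size != self.n_bins:
            raise ValueError("n_bins inconsistent with centers")
        if np.count_nonzero(np.abs(c) < 1e-9 * max(self.delta_v, 1e-300)) != 1:
            raise ValueError("axis must contain exactly one zero center")

    @property
    def zero_index(self) -> int:
        return int(np.argmin(np.abs(self.centers)))

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.n_bins) - self.zero_index

    @property
    def span(self) -> float:
        """Alias period (unaliased full width), cm/s."""
        return self.n_bins * self.delta_v

    def wrap(self, v: float | np.ndarray) -> np.ndarray:
        """Map physical velocities (cm/s) into the unaliased range."""
        w = self.span
        lo = self.centers[0] - self.delta_v / 2
        return (np.asarray(v) - lo) % w + lo

    def bin_of(self, v: float | np.ndarray) -> np.ndarray:
        """Index of the bin a physical velocity aliases into."""
        vw = self.wrap(v)
        return np.rint(vw / self.delta_v).astype(int) + self.zero_index


def _effective_sign(train: PulseTrain) -> np.ndarray:
    """Sign of the effective gradient at each waveform midpoint sample.

    Starts at +1 and flips after each refocusing (180°) pulse.
    """
    t = train.times
    sign = np.ones_like(t)
    for tr in train.refocusing_times():
        sign[t >= tr] *= -1.0
    return sign


def compute_effective_moments(train: PulseTrain) -> Moments:
    """Zeroth/first moments of the effective gradient, about t = 0.

    m0 = ∫G_eff dt, m1 = ∫G_eff·t dt; the accumulated transverse phase of
    a spin at constant velocity v starting at x0 is γ·(m0·x0 + m1·v).
    """
    s = _effective_sign(train)
    g = train.gradient * s
    t = train.times
    m0 = float(np.sum(g) * train.dt)
    m1 = float(np.sum(g * t) * train.dt)
    return Moments(m0=m0, m1=m1, kv=GAMMA * m1)


#: Default total duration of the preparation at gap_scale=1, s.
DEFAULT_DURATION = 0.045
#: Fixed gap between RF events and adjacent gradient lobes, s.
RF_GRAD_GAP = 0.5e-3
#: Default waveform sample spacing, s.
DEFAULT_DT = 1e-5


def build_train(
    m1_target: float,
    max_grad: float = 0.04,
    gap_scale: float = 1.0,
    tip_axis: TipAxis = TipAxis.cos_variant,
    dt: float = DEFAULT_DT,
) -> PulseTrain:
    """Construct a 90y–blip–180x–blip–180x–blip–180x–blip–tip-up train.

    Four rectangular gradient blips of equal physical amplitude sit midway
    between the RF pulses; with the refocusing sign pattern (+,−,+,−) their
    effective zeroth moment cancels exactly while the first moment is
    m1 = −A·δ·(c1−c2+c3−c4) ≈ 2·A·δ·q for inter-pulse period q, blip width
    δ and amplitude A. Lengthening the gaps (gap_scale > 1) stretches q and
    raises the achievable |m1| at fixed amplitude, which is how the base
    velocity-selective pulse is modified to reach finer velocity resolution.

    The blip width is chosen as the narrowest realizable at max_grad, and
    the amplitude is then solved exactly from the discrete lobe centers so
    that the effective m1 equals m1_target to machine precision.
    """
    if gap_scale < 1:
        raise ValueError("gap_scale must be >= 1")
    if max_grad <= 0:
        raise ValueError("max_grad must be positive")
    # Quarter period between RF pulses, snapped to the sample grid.
    q_samples = int(round(DEFAULT_DURATION / 4 * gap_scale / dt))
    q = q_samples * dt
    duration = 4 * q
    n_total = 4 * q_samples
    gap_samples = int(round(RF_GRAD_GAP / dt))
    max_blip = q_samples - 2 * gap_samples
    if max_blip < 1:
        raise InfeasibleTrainError("RF-gradient gaps leave no room for blips")

    gradient = np.zeros(n_total)
    if m1_target != 0.0:
        # Continuous-design width at full amplitude, then round up to samples.
        delta_needed = abs(m1_target) / (max_grad * 2 * q)
        n_blip = max(1, int(np.ceil(delta_needed / dt - 1e-9)))
        if n_blip > max_blip:
            raise InfeasibleTrainError(
                f"|m1_target|={abs(m1_target):.3e} T·s²/m needs a blip of "
                f"{n_blip * dt * 1e3:.2f} ms at max_grad={max_grad} T/m, but only "
                f"{max_blip * dt * 1e3:.2f} ms fits between RF pulses "
                "(limiting constraint: blip width vs inter-pulse gap)"
            )
        starts, centers = [], []
        for i in range(4):
            start = i * q_samples + (q_samples - n_blip) // 2
            starts.append(start)
            centers.append((start + n_blip / 2) * dt)
        # Effective centers alternate +,−,+,− after the three refocusing pulses.
        center_sum = centers[0] - centers[1] + centers[2] - centers[3]
        amp = m1_target / (n_blip * dt * center_sum)
        if abs(amp) > max_grad * (1 + 1e-9):
            raise InfeasibleTrainError(
                "discrete blip placement requires amplitude above max_grad"
            )
        for start in starts:
            gradient[start : start + n_blip] = amp

    flip_tip = -np.pi / 2 if tip_axis is TipAxis.cos_variant else np.pi / 2
    axis_tip = "y" if tip_axis is TipAxis.cos_variant else "x"
    rf_events = (
        (0.0, np.pi / 2, "y"),
        (q, np.pi, "x"),
        (2 * q, np.pi, "x"),
        (3 * q, np.pi, "x"),
        (duration, flip_tip, axis_tip),
    )
    return PulseTrain(
        rf_events=rf_events,
        tip_axis=tip_axis,
        gradient=gradient,
        dt=dt,
        duration=duration,
    )


def make_ladder(
    n_encodes: int, m1_max: float, scheme: LadderScheme | str = LadderScheme.half
) -> MomentLadder:
    """Build a uniform moment ladder.

    half: n values 0..m1_max (conjugate symmetry supplies negative moments).
    full: symmetric about 0 for odd n; for even n the extra step is positive.
    asymmetric: even-n full ladder with zero at index ceil(n/2)−1, i.e. one
    extra positive step — the pattern behind the printed −8.06..+8.64 cm/s
    30-bin axis.
    """
    scheme = LadderScheme(scheme)
    if n_encodes < 1:
        raise ValueError("n_encodes must be >= 1")
    if n_encodes == 1:
        if scheme is not LadderScheme.half:
            raise ValueError("a single encode is only valid for the half scheme")
        return MomentLadder(
            m1_values=np.array([0.0]),
            scheme=scheme,
            zero_index=0,
            delta_m1=0.0,
            m1_max=0.0,
        )
    if m1_max <= 0:
        raise ValueError("m1_max must be positive for n_encodes > 1")

    if scheme is LadderScheme.half:
        delta = m1_max / (n_encodes - 1)
        k = np.arange(n_encodes)
        zero_index = 0
    else:
        n = n_encodes
        zero_index = int(np.ceil(n / 2)) - 1
        k = np.arange(n) - zero_index
        delta = m1_max / k.max()
    values = k * delta
    return MomentLadder(
        m1_values=values,
        scheme=scheme,
        zero_index=int(zero_index),
        delta_m1=float(delta),
        m1_max=float(np.max(np.abs(values))),
    )


def completed_ladder(ladder: MomentLadder) -> MomentLadder:
    """Symmetric full ladder obtained by conjugate-completing a half ladder."""
    if ladder.scheme is not LadderScheme.half:
        raise ValueError("only half ladders are completed")
    n = len(ladder)
    if n == 1:
        return ladder
    k = np.arange(-(n - 1), n)
    return MomentLadder(
        m1_values=k * ladder.delta_m1,
        scheme=LadderScheme.full,
        zero_index=n - 1,
        delta_m1=ladder.delta_m1,
        m1_max=ladder.m1_max,
    )


def velocity_axis(ladder: MomentLadder) -> VelocityAxis:
    """Fourier-dual velocity grid of a (completed) moment ladder.

    For N moment samples at spacing Δm1 the decoded spectrum lives on N
    bins of width ΔV = 2π/(γ·N·Δm1), alias period N·ΔV = 2π/(γ·Δm1) — i.e.
    the unaliased half-width v_max = π/(γ·Δm1) follows the step size, and
    the bin width follows the extent of sampled velocity k-space. A half
    ladder of n encodes is completed to N = 2n−1 bins.
    """
    if len(ladder) > 1 and ladder.delta_m1 == 0.0:
        raise ValueError("degenerate ladder: zero m1 step with multiple encodes")
    if ladder.scheme is LadderScheme.half:
        full = completed_ladder(ladder)
    else:
        full = ladder
    n_bins = len(full)
    if n_bins == 1:
        return VelocityAxis(
            centers=np.array([0.0]), delta_v=0.0, v_max=0.0, n_bins=1
        )
    delta_v = 2 * np.pi / (GAMMA * n_bins * full.delta_m1)  # m/s
    centers = full.indices * delta_v
    return VelocityAxis(
        centers=si_to_cms(centers),
        delta_v=si_to_cms(delta_v),
        v_max=si_to_cms(n_bins * delta_v / 2),
        n_bins=n_bins,
    )


def ladder_for_axis(
    n_encodes: int,
    scheme: LadderScheme | str,
    delta_v_cm_s: float | None = None,
    v_max_cm_s: float | None = None,
) -> MomentLadder:
    """Build the ladder whose velocity axis has the requested resolution.

    Because the absolute first moment per gradient amplitude depends on
    unpublished blip timings, protocols are specified by their velocity
    sampling (bin width ΔV or unaliased half-width v_max) and inverted to
    moments: Δm1 = 2π/(γ·N·ΔV) = π/(γ·v_max).
    """
    scheme = LadderScheme(scheme)
    n_bins = 2 * n_encodes - 1 if scheme is LadderScheme.half else n_encodes
    if (delta_v_cm_s is None) == (v_max_cm_s is None):
        raise ValueError("specify exactly one of delta_v_cm_s, v_max_cm_s")
    if delta_v_cm_s is not None:
        delta_v = delta_v_cm_s * 0.01
        delta_m1 = 2 * np.pi / (GAMMA * n_bins * delta_v)
    else:
        v_max = v_max_cm_s * 0.01
        delta_m1 = np.pi / (GAMMA * v_max)
    if scheme is LadderScheme.half:
        m1_max = (n_encodes - 1) * delta_m1
    else:
        zero_index = int(np.ceil(n_encodes / 2)) - 1
        m1_max = (n_encodes - 1 - zero_index) * delta_m1
    return make_ladder(n_encodes, m1_max, scheme)


def bvalue(train: PulseTrain) -> float:
    """Diffusion weighting b = γ²∫[∫G_eff]² dt of the preparation, s/mm².

    The velocity-encoding blips unavoidably diffusion-weight the signal;
    for these preparations b stays small (tens of s/mm² at most).
    """
    s = _effective_sign(train)
    g = train.gradient * s
    # Cumulative integral at midpoint samples: F_i = ∫_0^{t_i} G_eff dτ.
    F = np.cumsum(g) * train.dt - g * train.dt / 2
    b_si = GAMMA**2 * float(np.sum(F**2) * train.dt)  # s/m²
    return b_si * 1e-6  # s/mm²
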