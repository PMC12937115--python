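"""Ground-truth flow phantoms on voxel grids.

Two laboratory phantoms are emulated: an array of eight parallel tubes of
graded diameter sharing one pressure drop (so, by Poiseuille's law, tube
peak velocity scales with diameter squared), immersed in a stationary
water bath; and a tubing loop whose two limbs carry equal and opposite
flow. Each voxel carries a velocity density — the fraction of its spins in
each bin of a velocity axis — with laminar tubes contributing a
skewed-parabola or uniform density on [0, Vmax] and stationary water a
delta at zero. Partial-volume voxels at tube walls get supersampled
mixtures.

Densities are bin-integrated (exact cumulative-distribution differences
per bin), not point-sampled, and velocities beyond the axis half-width are
wrapped into their alias bins so that the stored truth is exactly what the
finite moment ladder can represent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .physics import VelocityAxis


class GeometryError(ValueError):
    """Phantom geometry is impossible (overlapping or out-of-bounds tubes)."""


@dataclass(frozen=True)
class DensityVector:
    """Normalized velocity density on an axis (fractions sum to 1)."""

    axis: VelocityAxis
    fractions: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.size != self.axis.n_bins:
            raise ValueError("fractions length must match axis bins")
        if np.any(f < -1e-12):
            raise ValueError("fractions must be non-negative")
        object.__setattr__(self, "fractions", f)

    def centroid(self) -> float:
        """Density-weighted mean velocity, cm/s."""
        return float(np.sum(self.axis.centers * self.fractions))


@dataclass(frozen=True)
class TubeSpec:
    """One cylindrical flow tube (axis along z, circular cross-section)."""

    center: tuple[float, float]  # (y, x) mm in the slice plane
    diameter: float  # mm
    flow_sign: int
    v_mean: float  # cm/s

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be ±1")

    @property
    def v_max_tube(self) -> float:
        """Poiseuille peak (centerline) velocity = 2 × mean, cm/s."""
        return 2.0 * self.v_mean


@dataclass
class PhantomImage:
    """Voxel grid of ground-truth velocity densities.

    densities has shape (nz, ny, nx, n_bins); labels are 0 background,
    1 bath, 2+i tube i. tube_fractions holds the supersampled in-plane
    partial-volume fraction of each tube (z-uniform geometry).
    """

    densities: np.ndarray
    axis: VelocityAxis
    labels: np.ndarray
    voxel_size_mm: float
    tubes: list[TubeSpec] = field(default_factory=list)
    tube_fractions: np.ndarray | None = None  # (n_tubes, ny, nx)
    in_phantom: np.ndarray | None = None  # (nz, ny, nx) bool

    @property
    def shape(self):
        return self.densities.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return a


def laminar_profile(v: np.ndarray, v_max_tube: float, model: str = "paper") -> np.ndarray:
    """Continuous laminar velocity density, normalized to unit integral.

    model="paper": ρ(v) = 1.5/Vmax · sqrt(1 − v/Vmax) on [0, Vmax] — the
    monotone-decreasing skewed parabola. model="uniform_area": the standard
    spin-count Poiseuille density, constant 1/Vmax on [0, Vmax] (each
    velocity carries equal annular area, so the mean is exactly Vmax/2).
    """
    v = np.asarray(v, dtype=float)
    inside = (v >= 0) & (v <= v_max_tube)
    if model == "paper":
        out = np.where(inside, 1.5 / v_max_tube * np.sqrt(np.clip(1 - v / v_max_tube, 0, None)), 0.0)
    elif model == "uniform_area":
        out = np.where(inside, 1.0 / v_max_tube, 0.0)
    else:
        raise ValueError(f"unknown laminar model {model!r}")
    return out


def _laminar_cdf(v: np.ndarray, v_max_tube: float, model: str) -> np.ndarray:
    x = np.clip(np.asarray(v, dtype=float) / v_max_tube, 0.0, 1.0)
    if model == "paper":
        return 1.0 - (1.0 - x) ** 1.5
    if model == "uniform_area":
        return x
    raise ValueError(f"unknown laminar model {model!r}")


def laminar_density(
    v_max_tube: float,
    axis: VelocityAxis,
    model: str = "paper",
    flow_sign: int = 1,
) -> DensityVector:
    """Bin-integrate the laminar density onto a velocity axis, with aliasing.

    Mass at physical velocities beyond the axis half-width wraps modulo the
    alias period into the bins a Fourier decode would place it in, so the
    returned truth is directly comparable with reconstructed spectra.
    """
    if v_max_tube <= 0:
        raise ValueError("v_max_tube must be positive")
    if axis.n_bins == 1:
        return DensityVector(axis=axis, fractions=np.array([1.0]))
    if v_max_tube < axis.delta_v:
        warnings.warn(
            "tube velocity range smaller than one bin: all mass lands in the "
            "bins nearest zero",
            stacklevel=2,
        )
    W = axis.span
    edges_lo = axis.centers - axis.delta_v / 2
    edges_hi = axis.centers + axis.delta_v / 2
    if flow_sign < 0:
        # ρ₋(v) = ρ₊(−v): integrate the positive-support density over the
        # mirrored bin windows.
        edges_lo, edges_hi = -edges_hi, -edges_lo
    fractions = np.zeros(axis.n_bins)
    r_min = int(np.floor((0 - edges_hi.max()) / W)) - 1
    r_max = int(np.ceil((v_max_tube - edges_lo.min()) / W)) + 1
    for r in range(r_min, r_max + 1):
        lo = np.clip(edges_lo + r * W, 0.0, v_max_tube)
        hi = np.clip(edges_hi + r * W, 0.0, v_max_tube)
        fractions += _laminar_cdf(hi, v_max_tube, model) - _laminar_cdf(lo, v_max_tube, model)
    fractions = np.clip(fractions, 0.0, None)
    return DensityVector(axis=axis, fractions=fractions / fractions.sum())


def delta_density(axis: VelocityAxis, v: float = 0.0) -> DensityVector:
    """All mass in the bin a physical velocity v (cm/s) aliases into."""
    f = np.zeros(axis.n_bins)
    f[axis.bin_of(v)] = 1.0
    return DensityVector(axis=axis, fractions=f)


def _tube_fractions_2d(
    shape_yx: tuple[int, int],
    voxel: float,
    tubes: list[TubeSpec],
    supersample: int,
) -> np.ndarray:
    """In-plane partial-volume fraction of each tube per voxel (supersampled)."""
    ny, nx = shape_yx
    y = (np.arange(ny) - (ny - 1) / 2) * voxel
    x = (np.arange(nx) - (nx - 1) / 2) * voxel
    off = ((np.arange(supersample) + 0.5) / supersample - 0.5) * voxel
    ys = (y[:, None] + off[None, :]).ravel()  # ny*s
    xs = (x[:, None] + off[None, :]).ravel()
    fracs = np.zeros((len(tubes), ny, nx))
    for i, tube in enumerate(tubes):
        cy, cx = tube.center
        r2 = (tube.diameter / 2) ** 2
        inside = ((ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2) <= r2
        # collapse the supersample axes
        inside = inside.reshape(ny, supersample, nx, supersample)
        fracs[i] = inside.mean(axis=(1, 3))
    return fracs


def _check_geometry(tubes: list[TubeSpec], extent_y: float, extent_x: float, bath_radius: float | None):
    for i, a in enumerate(tubes):
        for b in tubes[i + 1 :]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < (a.diameter + b.diameter) / 2:
                raise GeometryError("tubes overlap")
        r = np.hypot(*a.center) + a.diameter / 2
        if bath_radius is not None and r > bath_radius:
            raise GeometryError("tube extends outside the bath chamber")
        if abs(a.center[0]) + a.diameter / 2 > extent_y / 2 or abs(a.center[1]) + a.diameter / 2 > extent_x / 2:
            raise GeometryError("tube extends outside the grid")


def render_phantom(
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    tubes: list[TubeSpec],
    axis: VelocityAxis,
    model: str = "paper",
    supersample: int = 4,
    bath: str = "sphere",
) -> PhantomImage:
    """Render tubes + stationary bath onto a voxel grid.

    bath="sphere" places the water chamber as a centered sphere (voxels
    with center outside it carry no signal); bath="full" floods the whole
    grid with stationary water (convenient for geometry checks).
    """
    nz, ny, nx = shape
    extent = (nz * voxel_size_mm, ny * voxel_size_mm, nx * voxel_size_mm)
    bath_radius = None
    if bath == "sphere":
        bath_radius = 0.48 * min(extent)
    elif bath != "full":
        raise ValueError(f"unknown bath geometry {bath!r}")
    _check_geometry(tubes, extent[1], extent[2], bath_radius)

    fracs = _tube_fractions_2d((ny, nx), voxel_size_mm, tubes, supersample)
    total = fracs.sum(axis=0)
    if np.any(total > 1 + 1e-9):
        raise GeometryError("tube fractions exceed 1 (overlap)")

    if bath == "sphere":
        z = (np.arange(nz) - (nz - 1) / 2) * voxel_size_mm
        y = (np.arange(ny) - (ny - 1) / 2) * voxel_size_mm
        x = (np.arange(nx) - (nx - 1) / 2) * voxel_size_mm
        rr = (
            z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
        )
        in_phantom = rr <= bath_radius**2
    else:
        in_phantom = np.ones(shape, dtype=bool)

    densities = np.zeros(shape + (axis.n_bins,))
    zero_bin = axis.zero_index
    bath_frac = np.clip(1.0 - total, 0.0, 1.0)
    densities[..., zero_bin] = bath_frac[None, :, :]
    for i, tube in enumerate(tubes):
        dv = laminar_density(tube.v_max_tube, axis, model=model, flow_sign=tube.flow_sign)
        densities += fracs[i][None, :, :, None] * dv.fractions
    densities *= in_phantom[..., None]

    labels = np.zeros(shape, dtype=np.int16)
    labels[in_phantom] = 1
    for i in range(len(tubes)):
        tube_mask = (fracs[i] > 0.5)[None, :, :] & in_phantom
        labels[tube_mask] = 2 + i
    return PhantomImage(
        densities=densities,
        axis=axis,
        labels=labels,
        voxel_size_mm=voxel_size_mm,
        tubes=list(tubes),
        tube_fractions=fracs,
        in_phantom=in_phantom,
    )


def multitube_specs(
    n_tubes: int = 8,
    d_min: float = 2.25,
    d_max: float = 4.0,
    calibration_mean: float = 7.24,
    spacing: float | None = None,
) -> list[TubeSpec]:
    """Tube table of the equal-pressure-drop array.

    Diameters are equally spaced d_min..d_max; at one shared pressure drop
    Poiseuille flow gives v_max ∝ d², so each tube's mean velocity is
    calibration_mean · (d/d_max)², anchored to the largest tube.
    """
    diameters = np.linspace(d_min, d_max, n_tubes)
    if spacing is None:
        spacing = 2.5 * d_max
    x0 = -(n_tubes - 1) / 2 * spacing
    specs = []
    for i, d in enumerate(diameters):
        specs.append(
            TubeSpec(
                center=(0.0, x0 + i * spacing),
                diameter=float(d),
                flow_sign=1,
                v_mean=float(calibration_mean * (d / d_max) ** 2),
            )
        )
    return specs


def build_multitube(
    axis: VelocityAxis,
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_mm: float = 2.0,
    n_tubes: int = 8,
    d_min: float = 2.25,
    d_max: float = 4.0,
    calibration_mean: float = 7.24,
    model: str = "paper",
    supersample: int = 4,
    bath: str = "sphere",
) -> PhantomImage:
    """The eight-tube equal-pressure phantom on a voxel grid."""
    specs = multitube_specs(n_tubes, d_min, d_max, calibration_mean)
    return render_phantom(shape, voxel_size_mm, specs, axis, model, supersample, bath)


def build_loop(
    axis: VelocityAxis,
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_mm: float = 2.0,
    tube_diameter: float = 12.7,
    v_mean: float = 1.0,
    separation: float | None = None,
    model: str = "paper",
    supersample: int = 4,
    bath: str = "sphere",
) -> PhantomImage:
    """Loop phantom: two parallel limbs with equal and opposite flow."""
    if separation is None:
        separation = shape[2] * voxel_size_mm / 3
    specs = [
        TubeSpec(center=(0.0, -separation / 2), diameter=tube_diameter, flow_sign=-1, v_mean=v_mean),
        TubeSpec(center=(0.0, +separation / 2), diameter=tube_diameter, flow_sign=1, v_mean=v_mean),
    ]
    return render_phantom(shape, voxel_size_mm, specs, axis, model, supersample, bath)
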