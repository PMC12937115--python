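import numpy as np
import pytest

import velspec as vs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def half31():
    """Human/loop protocol ladder: 31 half-Fourier encodes, 0.085 cm/s bins."""
    return vs.ladder_for_axis(31, "half", delta_v_cm_s=0.085)


@pytest.fixture(scope="session")
def asym30():
    """Phantom protocol ladder: 30 encodes, extra positive step, 0.576 cm/s."""
    return vs.ladder_for_axis(30, "asymmetric", delta_v_cm_s=0.576)


@pytest.fixture(scope="session")
def axis61(half31):
    return vs.velocity_axis(half31)


@pytest.fixture(scope="session")
def axis30(asym30):
    return vs.velocity_axis(asym30)


@pytest.fixture(scope="session")
def train_pair():
    """A cos/sin preparation pair with m1 = 2 µT·s²/m."""
    tc = vs.build_train(2.0e-6, 0.04, tip_axis=vs.TipAxis.cos_variant)
    ts = vs.build_train(2.0e-6, 0.04, tip_axis=vs.TipAxis.sin_variant)
    return tc, ts


def random_density_image(rng, shape, n_bins):
    dens = rng.random(shape + (n_bins,))
    return dens / dens.sum(axis=-1, keepdims=True)


def phantom_from_density(dens, axis, voxel=2.0):
    return vs.PhantomImage(
        densities=dens,
        axis=axis,
        labels=np.ones(dens.shape[:3], np.int16),
        voxel_size_mm=voxel,
    )


def tube_roi_mask(phantom, tube_index, frac_min=0.5, z_halfwidth=1):
    """Voxels in the central slices dominated by one tube."""
    nz = phantom.shape[0]
    m2d = phantom.tube_fractions[tube_index] >= frac_min
    mask = np.zeros(phantom.shape, bool)
    mask[nz // 2 - z_halfwidth : nz // 2 + z_halfwidth + 1] = m2d[None]
    if phantom.in_phantom is not None:
        mask &= phantom.in_phantom
    return mask
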