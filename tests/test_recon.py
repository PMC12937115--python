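"""Decoding pipeline stages and end-to-end spectrum recovery."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

import velspec as vs
from velspec.constants import GAMMA
from velspec.recon import VelocityKSpaceSeries, decode_spectrum, window_weights

from conftest import phantom_from_density, random_density_image, tube_roi_mask


def delta_series(ladder, v0_cm_s):
    """Velocity-k-space of a single spin population at physical v0."""
    vals = np.exp(1j * GAMMA * ladder.m1_values * v0_cm_s * 0.01).reshape(1, 1, 1, -1)
    return VelocityKSpaceSeries(values=vals, ladder=ladder)


@pytest.fixture(scope="module")
def full61():
    return vs.make_ladder(61, 2e-5, "full")


class TestRephaseCombine:
    def test_clean_series_unchanged(self, half31, axis61, rng):
        dens = random_density_image(rng, (2, 2, 2), 61)
        ser = vs.forward_encode(phantom_from_density(dens, axis61), half31)
        out, mask = vs.rephase(ser)
        assert mask.all()
        assert np.abs(out.frames - ser.frames).max() < 1e-15

    def test_low_signal_voxels_masked(self, half31, axis61):
        dens = np.zeros((2, 1, 1, 61))
        dens[0, ..., axis61.zero_index] = 1.0  # second voxel empty
        ser = vs.forward_encode(phantom_from_density(dens, axis61), half31)
        _, mask = vs.rephase(ser)
        assert mask[0, 0, 0] and not mask[1, 0, 0]

    def test_combine_stationary_voxel_is_all_ones(self, half31, axis61):
        dens = np.zeros((1, 1, 1, 61))
        dens[..., axis61.zero_index] = 1.0
        vks = vs.combine_pairs(vs.forward_encode(phantom_from_density(dens, axis61), half31))
        assert np.allclose(vks.values, 1.0)

    def test_combine_delta_gives_complex_exponential(self, half31, axis61):
        j = 45
        dens = np.zeros((1, 1, 1, 61))
        dens[..., j] = 1.0
        vks = vs.combine_pairs(vs.forward_encode(phantom_from_density(dens, axis61), half31))
        v0 = axis61.centers[j] * 0.01
        expected = np.exp(1j * GAMMA * half31.m1_values * v0)
        assert np.allclose(vks.values[0, 0, 0], expected, atol=1e-12)

    def test_missing_pair_member_rejected(self, half31, axis61):
        dens = random_density_image(np.random.default_rng(0), (1, 1, 1), 61)
        ser = vs.forward_encode(phantom_from_density(dens, axis61), half31)
        # overwrite one sin slot with a duplicate cos entry: pairing broken
        manifest = list(ser.frame_manifest)
        manifest[3] = (manifest[3][0], "cos")
        broken = vs.EncodedSeries(
            frames=ser.frames, frame_manifest=manifest, ladder=ser.ladder
        )
        with pytest.raises(ValueError, match="missing sin"):
            vs.combine_pairs(broken)


class TestDetrend:
    def test_constant_series_removed(self, full61):
        vals = np.full((1, 1, 1, 61), 2.5 + 0.5j)
        out = vs.detrend(VelocityKSpaceSeries(values=vals, ladder=full61))
        assert np.abs(out.values).max() < 1e-12

    def test_exact_cubic_removed(self, full61):
        k = np.linspace(-1, 1, 61)
        cubic = 0.3 - 0.2 * k + 0.7 * k**2 - 0.4 * k**3
        vals = (cubic * (1 + 0.5j)).reshape(1, 1, 1, -1)
        out = vs.detrend(VelocityKSpaceSeries(values=vals, ladder=full61))
        assert np.abs(out.values).max() < 1e-10

    def test_oscillating_component_preserved(self, full61):
        """A 6-cycle cosine loses < 2% amplitude to the cubic fit."""
        K = 61
        k = np.arange(K)
        sig = np.cos(2 * np.pi * 6 * k / K)
        vals = sig.reshape(1, 1, 1, -1).astype(complex)
        out = vs.detrend(VelocityKSpaceSeries(values=vals, ladder=full61))
        # independent least-squares projection oracle
        V = np.vander(np.linspace(-1, 1, K), 4)
        beta, *_ = np.linalg.lstsq(V, sig, rcond=None)
        expected = sig - V @ beta
        assert np.allclose(out.values[0, 0, 0].real, expected, atol=1e-10)
        assert np.linalg.norm(expected) > 0.98 * np.linalg.norm(sig)

    def test_too_short_series_rejected(self):
        lad = vs.make_ladder(4, 1e-5, "full")
        vals = np.ones((1, 1, 1, 4), dtype=complex)
        with pytest.raises(ValueError, match="too short"):
            vs.detrend(VelocityKSpaceSeries(values=vals, ladder=lad), order=3)


class TestSavitzkyGolay:
    def test_polynomial_invariance(self, full61):
        k = np.linspace(-1, 1, 61)
        poly = 1.0 + k - 0.5 * k**2 + 0.25 * k**3
        vals = poly.reshape(1, 1, 1, -1).astype(complex)
        out = vs.sg_smooth(VelocityKSpaceSeries(values=vals, ladder=full61), 7, 3)
        assert np.abs(out.values - vals).max() < 1e-10

    def test_window_one_is_identity(self, full61):
        vals = np.random.default_rng(0).normal(size=(1, 1, 1, 61)).astype(complex)
        out = vs.sg_smooth(VelocityKSpaceSeries(values=vals, ladder=full61), 1, 3)
        assert np.array_equal(out.values, vals)

    def test_invalid_window_rejected(self, full61):
        vals = np.ones((1, 1, 1, 61), dtype=complex)
        with pytest.raises(ValueError):
            vs.sg_smooth(VelocityKSpaceSeries(values=vals, ladder=full61), 6, 3)
        with pytest.raises(ValueError):
            vs.sg_smooth(VelocityKSpaceSeries(values=vals, ladder=full61), 3, 3)

    def test_white_noise_variance_reduction(self, full61, rng):
        """Interior-point variance shrinks by the sum of squared SG weights."""
        window, order = 7, 3
        vals = rng.normal(size=(100, 10, 10, 61)).astype(complex)
        out = vs.sg_smooth(VelocityKSpaceSeries(values=vals, ladder=full61), window, order)
        interior = out.values.real[..., window : 61 - window]
        factor = np.sum(savgol_coeffs(window, order) ** 2)
        assert interior.var() == pytest.approx(factor, rel=0.1)


class TestConjugateCompletion:
    def test_symmetry_by_construction(self, half31, axis61, rng):
        dens = random_density_image(rng, (1, 1, 1), 61)
        vks = vs.combine_pairs(vs.forward_encode(phantom_from_density(dens, axis61), half31))
        full = vs.conjugate_complete(vks)
        S = full.values[0, 0, 0]
        assert len(full.ladder) == 61
        assert np.allclose(S, np.conj(S[::-1]), atol=0)

    def test_completed_half_equals_direct_full(self, half31, axis61, rng):
        """Spectra from completed half data match directly sampled full data."""
        dens = random_density_image(rng, (2, 2, 1), 61)
        ph = phantom_from_density(dens, axis61)
        half_vks = vs.combine_pairs(vs.forward_encode(ph, half31))
        spec_half = decode_spectrum(vs.conjugate_complete(half_vks))
        full_lad = vs.completed_ladder(half31)
        full_vks = vs.combine_pairs(vs.forward_encode(ph, full_lad))
        spec_full = decode_spectrum(full_vks)
        assert np.abs(spec_half.spectra - spec_full.spectra).max() < 1e-10

    def test_sign_discrimination_from_half_data(self, half31, axis61):
        """Deltas at ±v0 decode to opposite-sign bins from half-sampled data."""
        for j, side in ((40, +1), (20, -1)):
            dens = np.zeros((1, 1, 1, 61))
            dens[..., j] = 1.0
            vks = vs.combine_pairs(vs.forward_encode(phantom_from_density(dens, axis61), half31))
            spec = decode_spectrum(vs.conjugate_complete(vks))
            peak = spec.spectra[0, 0, 0].argmax()
            assert peak == j
            assert np.sign(axis61.centers[peak]) == side

    def test_full_input_rejected(self, full61):
        vals = np.ones((1, 1, 1, 61), dtype=complex)
        with pytest.raises(ValueError, match="half"):
            vs.conjugate_complete(VelocityKSpaceSeries(values=vals, ladder=full61))


class TestWindow:
    def test_none_is_identity(self, full61):
        vals = np.random.default_rng(1).normal(size=(1, 1, 1, 61)).astype(complex)
        out = vs.apply_window(VelocityKSpaceSeries(values=vals, ladder=full61), "none")
        assert np.array_equal(out.values, vals)

    def test_peak_one_even_and_tapers_to_zero(self, full61):
        w = window_weights(full61, "hanning")
        assert w[full61.zero_index] == 1.0
        assert np.allclose(w, w[::-1])
        assert w[0] == pytest.approx(0.0, abs=1e-12)

    def test_windowed_delta_mainlobe_and_sidelobes(self, full61):
        """Windowing spreads a delta into a ~3-bin main lobe and pushes
        sidelobes below 1% of the peak."""
        axis = vs.velocity_axis(full61)
        j = 40
        vks = delta_series(full61, axis.centers[j])
        plain = decode_spectrum(vks).spectra[0, 0, 0]
        win = decode_spectrum(vs.apply_window(vks, "hanning")).spectra[0, 0, 0]
        assert plain.argmax() == j and win.argmax() == j
        # main lobe wider: immediate neighbours carry mass
        assert win[j - 1] > 0.1 * win[j] and win[j + 1] > 0.1 * win[j]
        far = np.abs(np.arange(61) - j) > 2
        assert win[far].max() < 0.01 * win[j]


class TestDecode:
    def test_exact_inversion_random_densities(self, full61, rng):
        """Unwindowed decode inverts the forward encode to 1e-10."""
        axis = vs.velocity_axis(full61)
        dens = random_density_image(rng, (5, 5, 4), 61)
        ph = phantom_from_density(dens, axis)
        vks = vs.combine_pairs(vs.forward_encode(ph, full61))
        spec = decode_spectrum(vks)
        assert np.abs(spec.spectra - dens).max() < 1e-10

    def test_stationary_voxel_all_mass_at_zero(self, full61):
        axis = vs.velocity_axis(full61)
        vks = delta_series(full61, 0.0)
        spec = decode_spectrum(vks).spectra[0, 0, 0]
        assert spec[axis.zero_index] == pytest.approx(1.0, abs=1e-12)
        assert np.delete(spec, axis.zero_index).max() < 1e-12

    def test_aliasing_law(self, full61, rng):
        """Deltas at arbitrary v0 (beyond ±v_max too) land in the bin given
        by wrapping v0 modulo the alias period."""
        axis = vs.velocity_axis(full61)
        for _ in range(100):
            j = int(rng.integers(0, 61))
            r = int(rng.integers(-2, 3))
            v0 = axis.centers[j] + r * axis.span
            spec = decode_spectrum(delta_series(full61, v0)).spectra[0, 0, 0]
            assert spec.argmax() == j
            assert spec.argmax() == axis.bin_of(v0)

    def test_half_ladder_rejected(self, half31):
        vals = np.ones((1, 1, 1, 31), dtype=complex)
        with pytest.raises(ValueError, match="full"):
            decode_spectrum(VelocityKSpaceSeries(values=vals, ladder=half31))


class TestNormalize:
    def test_sums_to_one_and_scale_invariant(self, full61, rng):
        axis = vs.velocity_axis(full61)
        spectra = rng.random((3, 3, 3, 61))
        img = vs.SpectrumImage(spectra=spectra, axis=axis)
        out = vs.normalize_spectrum(img)
        sums = out.spectra.sum(-1)
        assert np.allclose(sums[out.mask], 1.0, atol=1e-12)
        out7 = vs.normalize_spectrum(vs.SpectrumImage(spectra=7 * spectra, axis=axis))
        assert np.allclose(out.spectra, out7.spectra, atol=1e-12)

    def test_uniform_spectrum(self, full61):
        axis = vs.velocity_axis(full61)
        img = vs.SpectrumImage(spectra=np.full((1, 1, 1, 61), 3.0), axis=axis)
        out = vs.normalize_spectrum(img)
        assert np.allclose(out.spectra, 1 / 61)

    def test_zero_sum_voxel_masked_out(self, full61):
        axis = vs.velocity_axis(full61)
        spectra = np.zeros((2, 1, 1, 61))
        spectra[0] = 1.0
        img = vs.SpectrumImage(spectra=spectra, axis=axis)
        out = vs.normalize_spectrum(img, mask=np.ones((2, 1, 1), bool))
        assert out.mask[0, 0, 0] and not out.mask[1, 0, 0]


class TestGlobalRegression:
    def test_uniform_image_regresses_to_zero(self, full61, rng):
        axis = vs.velocity_axis(full61)
        base = rng.random(61)
        spectra = np.tile(base, (2, 2, 2, 1))
        img = vs.SpectrumImage(spectra=spectra, axis=axis)
        out = vs.global_mean_regress(img, np.ones((2, 2, 2), bool))
        assert np.abs(out.spectra).max() < 1e-10

    def test_orthogonal_component_recovered(self, full61, rng):
        axis = vs.velocity_axis(full61)
        gbar = rng.random(61)
        X = np.column_stack([np.ones(61), gbar])
        comp = rng.normal(size=61)
        comp -= X @ np.linalg.lstsq(X, comp, rcond=None)[0]  # orthogonalize
        spectra = np.tile(gbar, (3, 1, 1, 1)).astype(float)
        spectra[1, 0, 0] = gbar + comp
        img = vs.SpectrumImage(spectra=spectra, axis=axis)
        out = vs.global_mean_regress(img, np.ones((3, 1, 1), bool))
        resid = out.residual_raw[1, 0, 0]
        # OLS projection oracle: residual is orthogonal to [1, global mean]
        gbar_new = spectra.reshape(-1, 61).mean(0)
        Xn = np.column_stack([np.ones(61), gbar_new])
        assert np.abs(Xn.T @ resid).max() < 1e-8
        y = spectra[1, 0, 0]
        expected = y - Xn @ np.linalg.lstsq(Xn, y, rcond=None)[0]
        assert np.allclose(resid, expected, atol=1e-10)

    def test_single_voxel_mask_gives_zero_residual(self, full61, rng):
        axis = vs.velocity_axis(full61)
        spectra = rng.random((1, 1, 1, 61))
        img = vs.SpectrumImage(spectra=spectra, axis=axis)
        out = vs.global_mean_regress(img, np.ones((1, 1, 1), bool))
        assert np.abs(out.spectra).max() < 1e-10

    def test_zero_variance_regressor_rejected(self, full61):
        axis = vs.velocity_axis(full61)
        img = vs.SpectrumImage(spectra=np.ones((2, 1, 1, 61)), axis=axis)
        with pytest.raises(ValueError, match="variance"):
            vs.global_mean_regress(img, np.ones((2, 1, 1), bool))


class TestDetrendKillsStationaryPeak:
    def test_stationary_zero_peak_eliminated(self, half31, axis61):
        """Detrending removes the flat stationary component, so the
        zero-velocity peak disappears from the decoded spectrum."""
        dens = np.zeros((1, 1, 1, 61))
        dens[..., axis61.zero_index] = 0.8
        dens[..., 45] = 0.2  # a moving population
        ph = phantom_from_density(dens, axis61)
        ser = vs.forward_encode(ph, half31)
        with_dt = vs.reconstruct(ser, vs.ReconConfig(detrend_order=3, window="none", normalize=False))
        without = vs.reconstruct(ser, vs.ReconConfig(detrend_order=None, window="none", normalize=False))
        z = axis61.zero_index
        assert without.spectra[0, 0, 0, z] == pytest.approx(0.8, abs=1e-10)
        assert with_dt.spectra[0, 0, 0, z] < 0.05
        # the moving peak survives detrending
        assert with_dt.spectra[0, 0, 0, 45] > 0.15


class TestReconstructEndToEnd:
    def test_clean_full_recovery_exact(self, asym30, rng):
        axis = vs.velocity_axis(asym30)
        ph = vs.build_multitube(axis, shape=(8, 48, 48), bath="full", model="uniform_area")
        ser = vs.forward_encode(ph, asym30)
        img = vs.reconstruct(ser, vs.ReconConfig(detrend_order=None, window="none"))
        assert np.abs(img.spectra - ph.densities).max() < 1e-10

    def test_windowed_recovery_matches_windowed_truth(self, asym30):
        axis = vs.velocity_axis(asym30)
        ph = vs.build_multitube(axis, shape=(8, 48, 48), bath="full", model="uniform_area")
        ser = vs.forward_encode(ph, asym30)
        img = vs.reconstruct(ser, vs.ReconConfig(detrend_order=None, window="hanning"))
        for i in range(8):
            mask = tube_roi_mask(ph, i)
            roi = vs.roi_spectrum(img, mask)
            truth = ph.densities[mask].mean(0)
            wtruth = vs.windowed_density(vs.DensityVector(axis=axis, fractions=truth / truth.sum()))
            r = np.corrcoef(roi.fractions, wtruth.fractions)[0, 1]
            assert r > 0.99

    def test_loop_half_sampled_direction_discrimination(self, half31):
        """Opposite loop limbs put their spectral peaks in opposite-sign bins
        even though only non-negative moments were sampled."""
        axis = vs.velocity_axis(half31)
        ph = vs.build_loop(axis, shape=(8, 48, 48), v_mean=1.0, bath="full")
        ser = vs.forward_encode(ph, half31)
        img = vs.reconstruct(ser, vs.ReconConfig(detrend_order=None, window="hanning"))
        peaks = []
        for i in range(2):
            mask = tube_roi_mask(ph, i, frac_min=0.9)
            roi = vs.roi_spectrum(img, mask)
            nonzero = roi.fractions.copy()
            nonzero[axis.zero_index] = 0  # ignore stationary partial volume
            peaks.append(axis.centers[nonzero.argmax()])
        assert peaks[0] < 0 < peaks[1]


class TestRoiSpectrum:
    def test_identical_voxels_return_that_spectrum(self, full61, rng):
        axis = vs.velocity_axis(full61)
        base = rng.random(61)
        base /= base.sum()
        spectra = np.tile(base, (2, 2, 1, 1))
        img = vs.SpectrumImage(spectra=spectra, axis=axis, normalized=True)
        roi = vs.roi_spectrum(img, np.ones((2, 2, 1), bool))
        assert np.allclose(roi.fractions, base, atol=1e-12)

    def test_two_voxel_deltas_average_symmetrically(self, full61):
        axis = vs.velocity_axis(full61)
        spectra = np.zeros((2, 1, 1, 61))
        spectra[0, ..., 40] = 1.0
        spectra[1, ..., 20] = 1.0
        img = vs.SpectrumImage(spectra=spectra, axis=axis, normalized=True)
        roi = vs.roi_spectrum(img, np.ones((2, 1, 1), bool))
        assert roi.fractions[40] == pytest.approx(0.5)
        assert roi.fractions[20] == pytest.approx(0.5)

    def test_empty_mask_rejected(self, full61):
        axis = vs.velocity_axis(full61)
        img = vs.SpectrumImage(spectra=np.ones((1, 1, 1, 61)), axis=axis)
        with pytest.raises(ValueError, match="empty"):
            vs.roi_spectrum(img, np.zeros((1, 1, 1), bool))
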