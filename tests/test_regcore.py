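"""Unit and property tests for the phase-correlation registration core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailtrack import (
    DegenerateInputError,
    InvalidArgumentError,
    ShiftVector,
    VolumeImage,
    correlation_surface,
    cross_power_spectrum,
    estimate_shift,
    oracle_shift,
    subpixel_refine,
    wrap_to_signed,
)

from conftest import rolled


class TestVolumeImage:
    def test_rejects_small_dims(self, rng):
        with pytest.raises(InvalidArgumentError):
            VolumeImage(rng.random((4, 16, 16)), (1, 1, 1))

    def test_rejects_bad_voxel_size(self, rng):
        with pytest.raises(InvalidArgumentError):
            VolumeImage(rng.random((16, 16, 16)), (1, 0, 1))

    def test_rejects_nonfinite(self, rng):
        data = rng.random((16, 16, 16))
        data[0, 0, 0] = np.nan
        with pytest.raises(InvalidArgumentError):
            VolumeImage(data, (1, 1, 1))


class TestShiftVector:
    def test_micrometres_consistent_with_voxels(self):
        sv = ShiftVector.from_voxels((1.0, -2.0, 0.5), (2.0, 0.5, 0.5), 0.9)
        np.testing.assert_allclose(sv.micrometres, [2.0, -1.0, 0.25], atol=1e-9)

    def test_confidence_bounds_enforced(self):
        with pytest.raises(InvalidArgumentError):
            ShiftVector.from_voxels((0, 0, 0), (1, 1, 1), 1.5)


class TestCrossPowerSpectrum:
    def test_self_correlation_phase_is_zero(self, random_volume):
        spec = cross_power_spectrum(random_volume, random_volume, eps=1e-30)
        np.testing.assert_allclose(spec, np.ones_like(spec), atol=1e-9)

    def test_default_guard_downweights_but_keeps_phase(self, random_volume):
        """With the default guard, bins above it are unit modulus and every
        nonzero bin keeps zero phase for a self-pair."""
        spec = cross_power_spectrum(random_volume, random_volume)
        assert np.all(np.abs(spec) <= 1 + 1e-12)
        assert np.all(spec.real >= 0)
        np.testing.assert_allclose(spec.imag, 0.0, atol=1e-9)
        assert np.isclose(np.abs(spec).max(), 1.0)

    def test_integer_shift_gives_planar_phase_ramp(self, rng):
        """Fourier shift theorem: the spectrum of a shifted pair is a pure
        phase ramp exp(+2πi k·s/N) under the F(a)·conj(F(b)) definition."""
        a = VolumeImage(rng.random((8, 8, 8)), (1, 1, 1))
        s = (2, -3, 1)
        b = rolled(a, s)
        spec = cross_power_spectrum(a, b, eps=1e-30)
        freqs = [np.fft.fftfreq(n) for n in a.shape]
        kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
        expected = np.exp(2j * np.pi * (kz * s[0] + ky * s[1] + kx * s[2]))
        np.testing.assert_allclose(spec, expected, atol=1e-9)

    def test_all_zero_volumes_yield_zero_spectrum(self):
        z = VolumeImage(np.zeros((8, 8, 8)), (1, 1, 1))
        spec = cross_power_spectrum(z, z)
        assert np.all(spec == 0)

    def test_shape_mismatch_rejected(self, rng):
        a = VolumeImage(rng.random((8, 8, 8)), (1, 1, 1))
        b = VolumeImage(rng.random((8, 8, 16)), (1, 1, 1))
        with pytest.raises(InvalidArgumentError):
            cross_power_spectrum(a, b)


class TestCorrelationSurface:
    def test_self_peak_at_origin(self, random_volume):
        surface = correlation_surface(random_volume, random_volume, window=False)
        assert np.unravel_index(np.argmax(surface), surface.shape) == (0, 0, 0)

    def test_shift_peak_at_wrapped_index(self, rng):
        a = VolumeImage(rng.random((32, 32, 32)), (1, 1, 1))
        b = rolled(a, (3, -5, 2))
        surface = correlation_surface(a, b, window=False)
        peak = np.unravel_index(np.argmax(surface), surface.shape)
        assert peak == (3, 32 - 5, 2)

    def test_constant_inputs_give_flat_surface(self):
        c = VolumeImage(np.full((8, 8, 8), 3.0), (1, 1, 1))
        surface = correlation_surface(c, c, window=False)
        assert np.ptp(surface) < 1e-9


class TestWrapToSigned:
    @pytest.mark.parametrize(
        "index, dims, expected",
        [
            ((0, 0, 0), (32, 32, 32), (0, 0, 0)),
            ((29, 3, 16), (32, 32, 32), (-3, 3, -16)),
            ((15, 16, 0), (31, 31, 31), (15, -15, 0)),
        ],
    )
    def test_mapping(self, index, dims, expected):
        np.testing.assert_array_equal(
            wrap_to_signed(np.array(index), np.array(dims)), expected
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            wrap_to_signed(np.array([32, 0, 0]), np.array([32, 32, 32]))


class TestSubpixelRefine:
    def _surface_with_peak(self, samples, axis=2):
        surface = np.zeros((8, 8, 8))
        surface[0, 0, 0] = samples[1]
        idx_m = [0, 0, 0]
        idx_p = [0, 0, 0]
        idx_m[axis] = 7
        idx_p[axis] = 1
        surface[tuple(idx_m)] = samples[0]
        surface[tuple(idx_p)] = samples[2]
        return surface

    def test_symmetric_samples_give_zero(self):
        surface = self._surface_with_peak((0.5, 1.0, 0.5))
        np.testing.assert_allclose(subpixel_refine(surface, np.zeros(3, int)), 0.0)

    def test_parabolic_vertex_closed_form(self):
        # 0.5*(0.5-0.7)/(0.5-2.0+0.7) = 0.125
        surface = self._surface_with_peak((0.5, 1.0, 0.7))
        offsets = subpixel_refine(surface, np.zeros(3, int))
        assert offsets[2] == pytest.approx(0.125)

    def test_flat_samples_degenerate_to_zero(self):
        surface = np.ones((8, 8, 8))
        np.testing.assert_allclose(subpixel_refine(surface, np.zeros(3, int)), 0.0)


class TestEstimateShift:
    def test_identity(self, random_volume):
        sv = estimate_shift(random_volume, random_volume, window=False)
        np.testing.assert_allclose(sv.voxels, 0.0, atol=1e-9)
        assert sv.confidence > 0.9

    def test_exact_integer_shift(self, random_volume):
        b = rolled(random_volume, (3, -5, 2))
        sv = estimate_shift(random_volume, b, window=False, subpixel=False)
        np.testing.assert_array_equal(sv.voxels, [3, -5, 2])

    def test_micrometres_scale_with_voxel_size(self, rng):
        a = VolumeImage(rng.random((16, 16, 16)), (2.0, 0.5, 0.5))
        b = rolled(a, (1, 4, -2))
        sv = estimate_shift(a, b, window=False, subpixel=False)
        np.testing.assert_allclose(sv.micrometres, [2.0, 2.0, -1.0])

    def test_antisymmetry_for_integer_shifts(self, random_volume):
        b = rolled(random_volume, (2, -1, 4))
        fwd = estimate_shift(random_volume, b, window=False, subpixel=False)
        rev = estimate_shift(b, random_volume, window=False, subpixel=False)
        np.testing.assert_array_equal(fwd.voxels, -rev.voxels)

    def test_constant_pair_raises_degenerate(self):
        c = VolumeImage(np.full((8, 8, 8), 5.0), (1, 1, 1), frame_index=3)
        d = VolumeImage(np.full((8, 8, 8), 7.0), (1, 1, 1), frame_index=7)
        with pytest.raises(DegenerateInputError, match="3"):
            estimate_shift(c, d)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        sz=st.integers(-3, 3),
        sy=st.integers(-3, 3),
        sx=st.integers(-3, 3),
    )
    def test_integer_part_matches_bruteforce_oracle(self, seed, sz, sy, sx):
        """Exhaustive spatial-domain cross-correlation agrees with the FFT
        estimator on random shifted pairs."""
        gen = np.random.default_rng(seed)
        a = VolumeImage(gen.random((8, 8, 8)), (1, 1, 1))
        b = rolled(a, (sz, sy, sx))
        est = estimate_shift(a, b, window=False, subpixel=False)
        np.testing.assert_array_equal(est.voxels, oracle_shift(a, b))


class TestSubpixelAccuracy:
    @staticmethod
    def _blob_volume(rng, shape=(24, 24, 24), sigma=1.8, n_blobs=6):
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        data = np.zeros(shape)
        centres = rng.uniform(4, np.array(shape) - 4, size=(n_blobs, 3))
        for c in centres:
            data += np.exp(
                -((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
                / (2 * sigma**2)
            )
        return data

    @staticmethod
    def _fourier_shift(data, shift):
        import scipy.ndimage

        return np.fft.ifftn(
            scipy.ndimage.fourier_shift(np.fft.fftn(data), shift)
        ).real

    def test_fractional_shift_recovered_within_quarter_voxel(self, rng):
        """Band-limited blobs translated by fractional shifts are recovered
        to <= 0.25 voxel per axis at 5% noise (20 trials).  Fourier-shifted
        data is circularly periodic, so the window stays off."""
        worst = 0.0
        for trial in range(20):
            data = self._blob_volume(rng)
            true = rng.uniform(-2.5, 2.5, 3)
            moved = self._fourier_shift(data, true)
            noise_sd = 0.05 * data.max()
            a = VolumeImage(data + rng.normal(0, noise_sd, data.shape), (1, 1, 1))
            b = VolumeImage(moved + rng.normal(0, noise_sd, data.shape), (1, 1, 1))
            est = estimate_shift(a, b, window=False, subpixel=True)
            worst = max(worst, np.abs(est.voxels - true).max())
        assert worst <= 0.25

    def test_noise_robust_integer_recovery(self, rng):
        """At 10% noise the integer shift is recovered in >= 95% of trials
        on default-FOV-sized blob volumes."""
        shape = (40, 192, 192)
        zz = np.arange(shape[0])[:, None, None]
        yy = np.arange(shape[1])[None, :, None]
        xx = np.arange(shape[2])[None, None, :]
        data = np.zeros(shape, dtype=np.float32)
        centres = rng.uniform(8, np.array(shape) - 8, size=(150, 3))
        for c in centres:
            data += np.exp(
                -((zz - c[0]) ** 2 / (2 * 0.75**2)
                  + (yy - c[1]) ** 2 / (2 * 1.5**2)
                  + (xx - c[2]) ** 2 / (2 * 1.5**2))
            ).astype(np.float32)
        noise_sd = 0.10 * float(data.max())
        hits = 0
        trials = 100
        antisym_worst = 0.0
        for t in range(trials):
            s = rng.integers(-6, 7, 3)
            moved = np.roll(data, tuple(s), axis=(0, 1, 2))
            a = VolumeImage(data + rng.normal(0, noise_sd, shape).astype(np.float32), (2, 0.5, 0.5))
            b = VolumeImage(moved + rng.normal(0, noise_sd, shape).astype(np.float32), (2, 0.5, 0.5))
            est = estimate_shift(a, b, window=True, subpixel=True)
            if np.array_equal(np.round(est.voxels), s):
                hits += 1
            if t < 5:
                rev = estimate_shift(b, a, window=True, subpixel=True)
                antisym_worst = max(antisym_worst, np.abs(est.voxels + rev.voxels).max())
        assert hits >= 0.95 * trials
        assert antisym_worst <= 0.5


class TestAgainstScikitImage:
    def test_matches_independent_phase_correlation(self, rng):
        """scikit-image's phase_cross_correlation agrees on integer-shift
        pairs (their shift registers moving onto reference, i.e. -ours)."""
        skimage_reg = pytest.importorskip("skimage.registration")
        a = VolumeImage(rng.random((16, 16, 16)), (1, 1, 1))
        for s in [(1, -2, 3), (0, 4, -4), (-3, 0, 1)]:
            b = rolled(a, s)
            ours = estimate_shift(a, b, window=False, subpixel=False)
            theirs = skimage_reg.phase_cross_correlation(
                a.data, b.data, normalization="phase"
            )[0]
            np.testing.assert_array_equal(ours.voxels, -theirs)
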