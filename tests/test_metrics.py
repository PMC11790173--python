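from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turingrowth.fixtures import generate_blob_image
from turingrowth.metrics import (
    BinaryImage,
    binarize,
    count_motifs,
    dft_magnitude_spectrum,
    postprocess_spectrum,
    radial_band_set,
    spectral_energy,
)


def flood_fill_count(binary: np.ndarray) -> int:
    """Brute-force 8-connected component count (independent oracle)."""
    binary = binary.astype(bool)
    seen = np.zeros_like(binary)
    h, w = binary.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not seen[i, j]:
                count += 1
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    y, x = queue.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and binary[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                queue.append((yy, xx))
    return count


class TestBinarize:
    def test_threshold_splits_values(self):
        img = np.array([[3.9, 4.1], [4.1, 3.9]])
        out = binarize(img, 4.0)
        assert np.array_equal(out.values, [[0, 1], [1, 0]])
        assert out.threshold == 4.0

    def test_all_zero_image(self):
        out = binarize(np.zeros((5, 5)), 0.5)
        assert out.values.sum() == 0

    def test_leopard_snapshot_foreground_fraction(self, leopard_history):
        bi = binarize(leopard_history.b_snapshots[-1], 4.0)
        assert 0.0 < bi.foreground_fraction < 1.0

    def test_non_binary_values_rejected(self):
        with pytest.raises(ValueError):
            BinaryImage(np.array([[0, 2]]), threshold=1.0)


class TestCountMotifs:
    def test_blank_image_counts_zero(self):
        assert count_motifs(np.zeros((16, 16))) == 0

    def test_seven_separated_blobs(self):
        img, centers = generate_blob_image(7, (256, 256), 30, seed=3)
        assert len(centers) == 7
        assert count_motifs(img) == 7

    def test_two_touching_blobs_merge_to_one(self):
        # one connected supra-threshold region -> a single motif
        yy, xx = np.mgrid[:64, :64]
        blob = lambda cy, cx: np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 6.0**2))
        merged = binarize(blob(32, 28) + blob(32, 36), 0.3)
        assert flood_fill_count(merged.values) == 1
        assert count_motifs(merged) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.3, 0.7))
    def test_binary_counts_match_flood_fill_oracle(self, seed, density):
        rng = np.random.default_rng(seed)
        binary = (rng.random((32, 32)) < density).astype(np.uint8)
        assert count_motifs(BinaryImage(binary, 0.5)) == flood_fill_count(binary)

    def test_greyscale_prominence_counting(self):
        img, _ = generate_blob_image(5, (128, 128), 35, seed=7)
        img += 0.02 * np.sin(np.linspace(0, 40, 128))[None, :]  # sub-tolerance ripple
        assert count_motifs(img) == 5


class TestSpectrum:
    def test_constant_image_has_dc_only(self):
        spec = dft_magnitude_spectrum(np.full((32, 32), 3.0))
        mag = spec.magnitude.copy()
        assert mag[16, 16] == pytest.approx(3.0 * 32 * 32)
        mag[16, 16] = 0.0
        assert np.allclose(mag, 0.0)

    def test_cosine_stripes_peak_at_expected_frequency(self):
        # vertical stripes of period 50 px on a 500-px axis -> index +/-10
        n = 500
        x = np.arange(n)
        img = 0.5 + 0.5 * np.cos(2 * np.pi * x / 50.0)[None, :] * np.ones((n, 1))
        mag = dft_magnitude_spectrum(img).magnitude.copy()
        mag[n // 2, n // 2] = 0.0
        peaks = np.argwhere(mag > 0.99 * mag.max())
        assert {tuple(p) for p in peaks} == {(n // 2, n // 2 - 10), (n // 2, n // 2 + 10)}

    def test_point_symmetry_for_real_images(self):
        rng = np.random.default_rng(2)
        img = rng.random((40, 40))
        mag = dft_magnitude_spectrum(img).magnitude
        # M(k) = M(-k): point reflection about the centre (even-size grids
        # wrap the Nyquist row/column)
        flipped = np.roll(np.flip(mag), 1, axis=(0, 1))
        assert np.allclose(mag, flipped, atol=1e-8)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(3)
        img = rng.random((24, 24))
        spec = dft_magnitude_spectrum(img)
        assert spectral_energy(spec) == pytest.approx(img.size * (img**2).sum(), rel=1e-10)

    def test_magnitudes_non_negative(self, leopard_history):
        spec = dft_magnitude_spectrum(binarize(leopard_history.b_snapshots[-1], 4.0))
        assert (spec.magnitude >= 0).all()


class TestPostprocess:
    def _spec(self, seed=4, shape=(32, 32)):
        rng = np.random.default_rng(seed)
        return dft_magnitude_spectrum(rng.random(shape))

    def test_normalized_maximum_is_one(self):
        out = postprocess_spectrum(self._spec())
        assert out.magnitude.max() == pytest.approx(1.0)
        assert out.state == "normalized"

    def test_threshold_zeroes_weak_bins(self):
        out = postprocess_spectrum(self._spec(), threshold_fraction=1 / 20)
        surviving = out.magnitude[out.magnitude > 0]
        assert (surviving >= 1 / 20).all()
        assert (out.magnitude == 0).any()
        assert out.state == "thresholded"

    def test_series_normalization_uses_shared_maximum(self):
        specs = [self._spec(seed) for seed in (1, 2, 3)]
        logged = [postprocess_spectrum(s) for s in specs]
        series_max = max(l.normalization for l in logged)
        out = [postprocess_spectrum(s, normalize_by="series_max", series_max=series_max)
               for s in specs]
        assert max(o.magnitude.max() for o in out) == pytest.approx(1.0)
        assert all(o.normalization == series_max for o in out)

    def test_invalid_threshold_fraction_rejected(self):
        with pytest.raises(ValueError):
            postprocess_spectrum(self._spec(), threshold_fraction=1.5)


class TestRadialBands:
    def test_dc_only_spectrum_has_empty_band_set(self):
        spec = postprocess_spectrum(
            dft_magnitude_spectrum(np.full((32, 32), 2.0)), log=False,
            threshold_fraction=1 / 20)
        bands, richness = radial_band_set(spec, n_bands=8)
        assert bands == set()
        assert richness == 0.0

    def test_two_scale_pattern_unions_single_scale_bands(self):
        """A pattern holding two periodicities occupies the annuli of both
        single-frequency patterns; its band set is also strictly richer than
        either one alone."""
        n = 128
        x = np.arange(n)
        coarse = np.cos(2 * np.pi * 5 * x / n)[None, :] * np.ones((n, 1))
        fine = np.cos(2 * np.pi * 24 * x / n)[None, :] * np.ones((n, 1))

        def bands(img):
            spec = postprocess_spectrum(
                dft_magnitude_spectrum(img), log=False, threshold_fraction=1 / 20)
            return radial_band_set(spec, n_bands=8)[0]

        b_coarse, b_fine, b_both = bands(coarse), bands(fine), bands(coarse + fine)
        assert b_coarse | b_fine <= b_both
        assert len(b_both) > len(b_coarse)
        assert len(b_both) > len(b_fine)

    def test_too_few_bands_rejected(self):
        spec = postprocess_spectrum(
            dft_magnitude_spectrum(np.random.default_rng(0).random((16, 16))))
        with pytest.raises(ValueError):
            radial_band_set(spec, n_bands=1)
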