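"""Image-operator contracts: rendering, normalization, similarity, scrambling."""

import numpy as np
import pytest
from scipy import ndimage

import contextmod as cm
from contextmod import stimuli


def _texture(shape=(128, 128), seed=1, smooth=3.0):
    """Smooth noise texture with photo-like (bounded) tails."""
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
    tex = np.clip((tex - tex.mean()) / tex.std(), -2.5, 2.5)
    tex = (tex - tex.min()) / np.ptp(tex)
    return cm.LuminanceImage(tex)


def _scene_coords(img):
    n = img.shape[0]
    c = (np.arange(n) - (n - 1) / 2) / img.pixels_per_degree
    x, y = np.meshgrid(c, c)
    return x, y


class TestRenderGratingScene:
    def test_same_context_annulus_contrast(self):
        """Michelson contrast in the pure-context annulus matches the nominal
        25 % surround contrast."""
        scene = cm.GratingScene(context_orientation="horizontal",
                                context_contrast=0.25, target_contrast=0.05)
        img = cm.render_grating_scene(scene)
        x, y = _scene_coords(img)
        mask = (np.hypot(x, y) > 7) & (np.hypot(x, y) < 9)
        for th in scene.target_angles:
            cx = 5 * np.cos(np.deg2rad(th))
            cy = 5 * np.sin(np.deg2rad(th))
            mask &= np.hypot(x - cx, y - cy) > 2.5
        sub = img.pixels[mask]
        michelson = (sub.max() - sub.min()) / (sub.max() + sub.min())
        assert michelson == pytest.approx(0.25, abs=0.02)

    def test_isolated_background_uniform(self):
        scene = cm.GratingScene(context_orientation="none",
                                target_contrast=0.1, target_quadrant=2)
        img = cm.render_grating_scene(scene)
        x, y = _scene_coords(img)
        outside = np.ones(img.shape, bool)
        for th in scene.target_angles:
            cx = 5 * np.cos(np.deg2rad(th))
            cy = 5 * np.sin(np.deg2rad(th))
            outside &= np.hypot(x - cx, y - cy) > 1.6
        assert np.allclose(img.pixels[outside], 0.5)

    @staticmethod
    def _spectral_peak(pixels):
        F = np.abs(np.fft.fftshift(np.fft.fft2(pixels - pixels.mean())))
        n = pixels.shape[0]
        ky, kx = np.unravel_index(np.argmax(F), F.shape)
        return ky - n // 2, kx - n // 2

    def test_different_context_spectrum_vertical_axis(self):
        """The orthogonal ('Different') context is a vertical grating: its
        dominant 2-D spectral peak sits on the horizontal-frequency axis."""
        scene = cm.GratingScene(context_orientation="vertical",
                                target_contrast=0.02)
        ky, kx = self._spectral_peak(cm.render_grating_scene(scene).pixels)
        assert ky == 0 and kx != 0

    def test_rotating_scene_swaps_context_spectra(self):
        """A 90-degree image rotation turns the Same-context spectrum into
        the Different-context spectrum."""
        same = cm.render_grating_scene(cm.GratingScene(
            context_orientation="horizontal", target_contrast=0.02))
        diff = cm.render_grating_scene(cm.GratingScene(
            context_orientation="vertical", target_contrast=0.02))
        rot = self._spectral_peak(np.rot90(same.pixels))
        assert rot == self._spectral_peak(diff.pixels)

    def test_rejects_zero_target_contrast_and_coarse_sampling(self):
        with pytest.raises(ValueError):
            cm.GratingScene(target_contrast=0.0)
        with pytest.raises(ValueError):
            cm.render_grating_scene(cm.GratingScene(target_contrast=0.1),
                                    pixels_per_degree=4)


class TestNormalizeImage:
    def test_targets_reached_and_idempotent(self):
        img = _texture(seed=2)
        out = cm.normalize_image(img, 0.52, 0.12)
        assert out.pixels.mean() == pytest.approx(0.52, abs=1e-6)
        assert out.pixels.std() == pytest.approx(0.12, abs=1e-6)
        twice = cm.normalize_image(out, 0.52, 0.12)
        assert np.allclose(twice.pixels, out.pixels, atol=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            cm.normalize_image(cm.LuminanceImage(np.full((8, 8), 0.3)))


class TestPixelwiseSimilarity:
    def test_identity_and_negation(self):
        img = _texture(seed=3)
        assert cm.pixelwise_similarity(img, img) == pytest.approx(1.0)
        neg = cm.LuminanceImage(1 - img.pixels)
        assert cm.pixelwise_similarity(img, neg) == pytest.approx(-1.0)

    def test_matches_flatten_then_pearson_oracle(self):
        a, b = _texture(seed=4), _texture(seed=5)
        expected = np.corrcoef(a.pixels.ravel(), b.pixels.ravel())[0, 1]
        assert cm.pixelwise_similarity(a, b) == pytest.approx(
            expected, abs=1e-12)

    def test_errors(self):
        img = _texture()
        with pytest.raises(ValueError):
            cm.pixelwise_similarity(img, cm.LuminanceImage(np.zeros((4, 4))))
        with pytest.raises(ValueError):
            cm.pixelwise_similarity(
                img, _texture(shape=(64, 64)))


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self):
        """Radially averaged amplitude after 500 iterations stays within 5 %
        of the original's (the mask is spectrally matched to the stimulus)."""
        img = cm.normalize_image(_texture(seed=6), 0.52, 0.12)
        scrambled = cm.phase_scramble(img, iterations=500, seed=0)
        assert scrambled.shape == img.shape

        def radial(pixels):
            A = np.abs(np.fft.fft2(pixels))
            f = np.fft.fftfreq(pixels.shape[0])
            k = np.hypot(*np.meshgrid(f, f)).ravel()
            bins = np.digitize(k, np.linspace(0, 0.5, 16))
            return np.array([A.ravel()[bins == i].mean() for i in range(1, 16)])

        r0, r1 = radial(img.pixels), radial(scrambled.pixels)
        assert np.all(np.abs(r1 - r0) / r0 < 0.05)

    def test_total_spectral_energy_preserved(self):
        img = cm.normalize_image(_texture(seed=7), 0.52, 0.12)
        out = cm.phase_scramble(img, iterations=20, seed=1)
        e0 = np.sum(np.abs(np.fft.fft2(img.pixels)) ** 2)
        e1 = np.sum(np.abs(np.fft.fft2(out.pixels)) ** 2)
        assert e1 == pytest.approx(e0, rel=0.02)

    def test_decorrelates_from_original(self):
        """Across seeds, scrambled noise textures share almost no pixelwise
        structure with the original."""
        img = cm.normalize_image(_texture(shape=(256, 256), seed=8, smooth=2),
                                 0.52, 0.10)
        corrs = [
            cm.pixelwise_similarity(img, cm.phase_scramble(
                img, iterations=10, seed=s))
            for s in range(20)
        ]
        assert np.all(np.abs(corrs) < 0.1)

    def test_reproducible_and_validates(self):
        img = _texture(seed=9)
        a = cm.phase_scramble(img, iterations=5, seed=3)
        b = cm.phase_scramble(img, iterations=5, seed=3)
        assert np.array_equal(a.pixels, b.pixels)
        with pytest.raises(ValueError):
            cm.phase_scramble(img, iterations=0, seed=0)


class TestSelectMorphPairs:
    def test_two_sd_rule_on_similarity_distribution(self):
        """Pairs beyond two SDs of the mean similarity are excluded."""
        rng = np.random.default_rng(0)
        sims = 0.8 + 0.014 * rng.standard_normal(16)
        sims[5] = 0.8 + 5 * 0.014 * 3
        kept = cm.select_morph_pairs(sims)
        mean, sd = sims.mean(), sims.std(ddof=1)
        expected = np.flatnonzero(np.abs(sims - mean) <= 2 * sd)
        assert np.array_equal(kept, expected)
        assert 5 not in kept

    def test_single_outlier(self):
        sims = [0.8] * 9 + [0.5]
        assert 9 not in cm.select_morph_pairs(sims)

    def test_all_equal_retained(self):
        assert np.array_equal(cm.select_morph_pairs([0.8, 0.8, 0.8]),
                              [0, 1, 2])

    def test_too_few(self):
        with pytest.raises(ValueError):
            cm.select_morph_pairs([0.8, 0.9])
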