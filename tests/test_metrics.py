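"""PSNR/SSIM oracles, profiles, bar contrast, set evaluation."""

import json

import numpy as np
import pytest

from mcftwin.metrics import (BarSpec, bar_contrast, circular_mask,
                             cross_section_profile, evaluate_set, psnr, ssim)


class TestPSNR:
    def test_identical_images_are_infinite(self, rng):
        a = rng.random((32, 32))
        assert psnr(a, a) == float("inf")

    def test_closed_form_quarter_mse(self):
        a = np.zeros((16, 16))
        b = np.full((16, 16), 0.5)
        assert psnr(a, b) == pytest.approx(10 * np.log10(1 / 0.25), abs=1e-6)
        assert psnr(a, b) == pytest.approx(6.0206, abs=1e-3)

    def test_closed_form_constant_offset(self, rng):
        a = rng.random((16, 16)) * 0.8
        b = a + 0.1
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-6)

    def test_symmetry_and_monotonicity_in_mse(self, rng):
        a = rng.random((16, 16))
        b = np.clip(a + 0.05, 0, 1)
        c = np.clip(a + 0.10, 0, 1)
        assert psnr(a, b) == psnr(b, a)
        assert psnr(a, b) > psnr(a, c)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSSIM:
    def test_identical_images_score_one(self, rng):
        a = rng.random((32, 32))
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_constant_zero_vs_one_closed_form(self):
        a = np.zeros((32, 32))
        b = np.ones((32, 32))
        c1 = 0.01**2
        expected = c1 / (1 + c1)  # sigma terms vanish; cross term 0
        assert ssim(a, b) == pytest.approx(expected, rel=1e-6)

    def test_anticorrelated_patterns_score_negative(self):
        gr, gc = np.mgrid[0:32, 0:32]
        a = 0.5 + 0.4 * np.sin(gr * 0.7) * np.cos(gc * 0.5)
        b = 1.0 - a  # anti-correlated, same mean
        assert ssim(a, b) < 0

    def test_symmetry(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_masked_and_unmasked_both_computable(self, rng):
        a = rng.random((48, 48))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        mask = circular_mask((48, 48), (23.5, 23.5), 18)
        full = ssim(a, b)
        masked = ssim(a, b, mask=mask)
        assert -1 <= masked <= 1 and -1 <= full <= 1
        assert masked != full


class TestCrossSectionProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((32, 32), 0.7)
        p = cross_section_profile(img, (5, 2), (5, 29), 50)
        assert np.abs(p - 0.7).max() < 1e-12

    def test_step_edge_profile_is_monotone(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        p = cross_section_profile(img, (10, 2), (10, 29), 60)
        assert np.all(np.diff(p) >= -1e-12)
        assert p[0] == 0.0 and p[-1] == 1.0

    def test_diagonal_on_ramp_is_linear(self):
        gr, gc = np.mgrid[0:64, 0:64]
        img = (gr + gc) / 126.0
        p = cross_section_profile(img, (4, 8), (50, 60), 100)
        t = np.linspace(0, 1, 100)
        expected = p[0] + t * (p[-1] - p[0])
        assert np.abs(p - expected).max() < 1e-6

    def test_out_of_bounds_endpoint_raises(self):
        with pytest.raises(ValueError):
            cross_section_profile(np.zeros((16, 16)), (0, 0), (20, 3), 10)


class TestBarContrast:
    def test_perfect_bars_have_unit_contrast(self):
        from mcftwin.scenes import generate_bar_target

        img, specs = generate_bar_target(64, [10])
        assert bar_contrast(img, specs[0]) == pytest.approx(1.0)

    def test_uniform_region_guarded_to_zero(self):
        spec = BarSpec(8.0, "vertical", (0, 16), (0, 20), (2.0, 10.0, 18.0))
        assert bar_contrast(np.zeros((32, 32)), spec) == 0.0

    def test_gaussian_blur_matches_fundamental_attenuation(self):
        # a blurred square wave keeps only its fundamental; Michelson contrast
        # -> 2 * (2/pi) * exp(-2 pi^2 sigma^2 / p^2)
        from scipy.ndimage import gaussian_filter

        period, sigma = 16, 4.0
        x = np.arange(256)
        wave = ((x % period) < period // 2).astype(float)
        img = np.tile(wave, (64, 1))
        blurred = gaussian_filter(img, sigma, mode="wrap")
        spec = BarSpec(float(period), "vertical", (8, 56), (96, 96 + 40),
                       (99.5, 115.5, 131.5))
        measured = bar_contrast(blurred, spec)
        expected = (4 / np.pi) * np.exp(-2 * np.pi**2 * sigma**2 / period**2)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_region_outside_image_raises(self):
        spec = BarSpec(8.0, "vertical", (0, 64), (0, 20), (2.0, 10.0, 18.0))
        with pytest.raises(ValueError):
            bar_contrast(np.zeros((32, 32)), spec)


class TestEvaluateSet:
    def test_identity_pairs_score_perfectly(self, rng, tmp_path):
        pairs = [{"id": i, "input_image": rng.random((16, 16))} for i in range(3)]
        for p in pairs:
            p["target_image"] = p["input_image"]
        table = evaluate_set(pairs, out_csv=tmp_path / "m.csv")
        per_image = table[~table.image_id.isin(["mean", "median", "std"])]
        assert np.all(np.isinf(per_image.psnr_db))
        assert np.all(per_image.ssim == 1.0)
        assert (tmp_path / "m.csv").exists()

    def test_summary_matches_independent_recomputation(self, rng):
        pairs = []
        for i in range(10):
            a = rng.random((24, 24))
            b = np.clip(a + rng.normal(0, 0.08, a.shape), 0, 1)
            pairs.append({"id": i, "input_image": a, "target_image": b})
        table = evaluate_set(pairs)
        # independent brute-force recomputation
        ps = [psnr(p["input_image"], p["target_image"]) for p in pairs]
        ss = [ssim(p["input_image"], p["target_image"]) for p in pairs]
        mean_row = table[table.image_id == "mean"].iloc[0]
        assert mean_row.psnr_db == pytest.approx(np.mean(ps), abs=1e-9)
        assert mean_row.ssim == pytest.approx(np.mean(ss), abs=1e-9)

    def test_empty_manifest_raises(self):
        with pytest.raises(ValueError):
            evaluate_set([])

    def test_unreadable_entries_skipped_but_not_all(self, rng, tmp_path):
        good = rng.random((16, 16))
        manifest = tmp_path / "pairs.json"
        from mcftwin.imageio import write_image

        write_image(tmp_path / "a.tiff", good)
        manifest.write_text(json.dumps([
            {"id": 0, "input": str(tmp_path / "a.tiff"), "target": str(tmp_path / "a.tiff")},
            {"id": 1, "input": str(tmp_path / "missing.tiff"), "target": str(tmp_path / "a.tiff")},
        ]))
        table = evaluate_set(manifest)
        per_image = table[~table.image_id.isin(["mean", "median", "std"])]
        assert len(per_image) == 1
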