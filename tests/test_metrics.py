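"""PSNR/SSIM/RMSE/FRC against independent brute-force oracles."""

import math

import numpy as np
import pytest

from zsdenoise import frc, psnr, report, rmse, ssim
from zsdenoise.metrics import _gaussian_window


# ------------------------------------------------------------------- oracles
def rmse_oracle(x, y):
    """Direct double-loop sum."""
    acc = 0.0
    h, w = x.shape
    for i in range(h):
        for j in range(w):
            acc += (x[i, j] - y[i, j]) ** 2
    return math.sqrt(acc / (h * w))


def ssim_oracle(x, y, peak=1.0, size=11, sigma=1.5):
    """Per-window evaluation of the SSIM formula, valid windows only."""
    w = _gaussian_window(size, sigma)
    c1, c2 = (0.01 * peak) ** 2, (0.03 * peak) ** 2
    h, wd = x.shape
    vals = []
    for i in range(h - size + 1):
        for j in range(wd - size + 1):
            px = x[i : i + size, j : j + size]
            py = y[i : i + size, j : j + size]
            mx, my = (w * px).sum(), (w * py).sum()
            vx = (w * px * px).sum() - mx * mx
            vy = (w * py * py).sum() - my * my
            vxy = (w * px * py).sum() - mx * my
            vals.append(
                ((2 * mx * my + c1) * (2 * vxy + c2))
                / ((mx * mx + my * my + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def frc_oracle(x, y):
    """Per-ring correlation accumulated frequency by frequency."""
    n = x.shape[0]
    f1, f2 = np.fft.fft2(x), np.fft.fft2(y)
    freqs = np.fft.fftfreq(n)
    num: dict[int, float] = {}
    d1: dict[int, float] = {}
    d2: dict[int, float] = {}
    for i in range(n):
        for j in range(n):
            k = int(round(math.hypot(freqs[i], freqs[j]) * n))
            if k > n // 2:
                continue
            num[k] = num.get(k, 0.0) + (f1[i, j] * np.conj(f2[i, j])).real
            d1[k] = d1.get(k, 0.0) + abs(f1[i, j]) ** 2
            d2[k] = d2.get(k, 0.0) + abs(f2[i, j]) ** 2
    out = np.zeros(n // 2 + 1)
    for k in sorted(num):
        den = math.sqrt(d1[k] * d2[k])
        out[k] = num[k] / den if den > 0 else 0.0
    return out


# --------------------------------------------------------------------- tests
class TestScalarMetrics:
    def test_rmse_zero_for_identical(self, random_image):
        assert rmse(random_image, random_image) == 0.0

    def test_rmse_of_constant_offset_equals_offset(self, random_image):
        shifted = random_image.pixels + 0.146
        assert rmse(random_image.pixels, shifted) == pytest.approx(0.146, rel=1e-12)

    def test_rmse_matches_brute_force(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert rmse(x, y) == pytest.approx(rmse_oracle(x, y), rel=1e-12)

    def test_psnr_closed_form_20db(self):
        # mse = 0.01 at peak 1 -> 10*log10(1/0.01) = 20 dB
        x = np.zeros((8, 8))
        y = np.full((8, 8), 0.1)
        assert psnr(x, y) == pytest.approx(20.0, rel=1e-12)

    def test_psnr_half_offset(self):
        x = np.zeros((8, 8))
        y = np.full((8, 8), 0.5)
        assert psnr(x, y) == pytest.approx(10 * math.log10(4), rel=1e-12)

    def test_psnr_identical_is_infinite(self, random_image):
        assert psnr(random_image, random_image) == math.inf

    def test_psnr_rejects_nonpositive_peak(self, random_image):
        with pytest.raises(ValueError, match="peak"):
            psnr(random_image, random_image, peak=0.0)

    def test_psnr_decreases_with_noise_level(self, rng):
        base = rng.random((64, 64)) * 0.5 + 0.25
        vals = []
        for sigma in (0.05, 0.1, 0.2):
            noisy = base + np.random.default_rng(7).normal(0, sigma, base.shape)
            vals.append(psnr(base, noisy))
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse(np.zeros((8, 8)), np.zeros((8, 9)))


class TestSSIM:
    def test_self_similarity_is_one(self, random_image):
        assert ssim(random_image, random_image) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(x, y) == pytest.approx(ssim(y, x), rel=1e-12)

    def test_matches_windowed_oracle(self, rng):
        x = np.tile(np.linspace(0, 0.9, 16), (16, 1))
        y = np.clip(x + 0.1, 0, 1)
        assert ssim(x, y) == pytest.approx(ssim_oracle(x, y), rel=1e-6)

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(5):
            x, y = rng.random((14, 14)), rng.random((14, 14))
            assert ssim(x, y) == pytest.approx(ssim_oracle(x, y), rel=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestFRC:
    def test_self_correlation_is_one_in_every_ring(self, rng):
        x = rng.random((32, 32))
        curve = frc(x, x)
        np.testing.assert_allclose(curve.correlation, 1.0, atol=1e-12)

    def test_matches_per_frequency_oracle(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        curve = frc(x, y)
        np.testing.assert_allclose(curve.correlation, frc_oracle(x, y), rtol=1e-9, atol=1e-12)

    def test_ring_radii_ascending_below_nyquist(self, rng):
        curve = frc(rng.random((32, 32)), rng.random((32, 32)))
        assert np.all(np.diff(curve.ring_radii) > 0)
        assert curve.ring_radii[-1] <= 0.5
        assert len(curve.ring_radii) == len(curve.correlation)

    def test_independent_noise_decorrelates_high_rings(self):
        a = np.random.default_rng(1).random((64, 64))
        b = np.random.default_rng(2).random((64, 64))
        curve = frc(a, b)
        high = curve.ring_radii > 0.25
        assert np.mean(np.abs(curve.correlation[high])) < 0.3

    def test_band_limited_images_cut_off_at_band_edge(self):
        rng = np.random.default_rng(3)
        n = 64

        def band_limited(seed):
            f = np.fft.fft2(np.random.default_rng(seed).random((n, n)))
            fr = np.hypot(*np.meshgrid(np.fft.fftfreq(n), np.fft.fftfreq(n), indexing="ij"))
            f[fr > 0.25] = 0.0
            img = np.fft.ifft2(f).real
            return img

        x = band_limited(3) + rng.normal(0, 0.01, (n, n))
        y = band_limited(4) + rng.normal(0, 0.01, (n, n))
        curve = frc(x, y)
        assert curve.cutoff_frequency <= 0.3

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            frc(np.full((16, 16), 0.3), np.zeros((16, 16)) + np.eye(16))

    def test_non_square_center_cropped(self, rng):
        x = rng.random((32, 48))
        curve = frc(x, x)
        assert len(curve.ring_radii) == 17  # 32 // 2 + 1 rings


class TestReport:
    def test_reference_free_identity(self, random_image):
        rep = report(random_image, random_image)
        assert rep.rmse == 0.0
        assert rep.ssim == pytest.approx(1.0, abs=1e-12)
        assert rep.regime == "reference-free"

    def test_reference_regime_labelled(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        c = rng.random((32, 32))
        rep = report(a, b, reference=c)
        assert rep.regime == "reference"
        assert rep.rmse == pytest.approx(rmse(b, c))

    def test_json_schema(self, rng):
        import json

        rep = report(rng.random((32, 32)), rng.random((32, 32)))
        parsed = json.loads(rep.to_json())
        assert set(parsed) == {
            "psnr_db",
            "ssim",
            "rmse",
            "frc_cutoff_cycles_per_pixel",
            "regime",
        }
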