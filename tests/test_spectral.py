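"""Power spectra, fractional-bin radial summation, synthetic patterns."""

import math

import numpy as np
import pytest

from l1agg.spectral import (PowerSpectrum2D, dominant_peak, power_spectrum,
                            radial_sum, smooth_radial, standardize_image,
                            synthetic_pattern)


def cosine_image(m: int, n: int = 128) -> np.ndarray:
    x = np.arange(n) / n
    return 0.5 + 0.4 * np.cos(2 * np.pi * m * x)[:, None] * np.ones((1, n))


class TestStandardize:
    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(0)
        img = rng.normal(5.0, 2.0, (32, 32))
        out = standardize_image(img)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_identity_on_unit_range(self):
        img = np.linspace(0, 1, 64).reshape(8, 8)
        np.testing.assert_allclose(standardize_image(img), img)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 3, (16, 16))
        np.testing.assert_allclose(standardize_image(-img),
                                   1.0 - standardize_image(img), atol=1e-14)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            standardize_image(np.ones((8, 8)))


class TestPowerSpectrum:
    def test_cosine_concentrates_at_its_mode(self):
        m = 7
        spec = power_spectrum(cosine_image(m), 1.0)
        p = spec.power.copy()
        p[0, 0] = 0.0
        idx = np.unravel_index(np.argmax(p), p.shape)
        assert idx in ((m, 0), (spec.power.shape[0] - m, 0))

    def test_parseval(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (64, 64))
        spec = power_spectrum(img, 1.0)
        # numpy forward transform is unscaled: sum p_k = N^2 * sum img^2
        assert spec.power.sum() == pytest.approx(
            img.size * np.sum(img ** 2), rel=1e-12)

    def test_even_in_k(self):
        rng = np.random.default_rng(3)
        spec = power_spectrum(rng.uniform(0, 1, (32, 32)), 1.0)
        p = spec.power
        flipped = np.flip(np.flip(p, 0), 1)
        np.testing.assert_allclose(p[1:, 1:], flipped[:-1, :-1], rtol=1e-10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.zeros((8, 9)), 1.0)


class TestRadialSum:
    def test_worked_fractional_bin_example(self):
        """k = 2*pi*(1,2)/1.93 -> k_cyc = sqrt(5)/1.93, bin coordinate
        j = 1 + 1023*(k_cyc/20) = 60.26, split 0.74/0.26 over bins 60/61."""
        w = 1.93
        n = 960
        spec = PowerSpectrum2D(power=np.zeros((n, n)), width_cm=w)
        spec.power[1, 2] = 1.0
        k_cyc = math.sqrt(5.0) / w
        j = 1.0 + 1023.0 * (k_cyc / 20.0)
        assert j == pytest.approx(60.26, abs=0.01)
        rs = radial_sum(spec)
        # 1-based bins 60 and 61 are 0-based indices 59 and 60
        assert rs.s[59] == pytest.approx(61.0 - j, abs=1e-9)
        assert rs.s[60] == pytest.approx(j - 60.0, abs=1e-9)
        assert rs.s.sum() == pytest.approx(1.0)

    def test_integer_landing_gets_full_weight(self):
        spec = PowerSpectrum2D(power=np.zeros((64, 64)), width_cm=1.0)
        rs0 = radial_sum(spec, n_bins=21, k_cyc_max=20.0)
        spec.power[5, 0] = 2.0          # k_cyc = 5 -> j = 1 + 20*(5/20) = 6
        rs = radial_sum(spec, n_bins=21, k_cyc_max=20.0)
        assert rs.s[5] == pytest.approx(2.0)
        assert np.count_nonzero(rs.s) == 1

    def test_weight_conservation(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 1, (64, 64))
        spec = power_spectrum(img, 1.0)
        rs = radial_sum(spec)
        kept = spec.power[spec.k_magnitude() <= 20.0 + 1e-12]
        assert rs.s.sum() == pytest.approx(kept.sum(), rel=1e-12)
        assert rs.n_dropped == spec.power.size - kept.size


class TestSmoothing:
    def test_zero_radius_is_identity(self):
        rng = np.random.default_rng(5)
        rs = radial_sum(power_spectrum(rng.uniform(0, 1, (32, 32)), 1.0))
        np.testing.assert_array_equal(smooth_radial(rs, 0.0).s, rs.s)

    def test_total_power_preserved(self):
        rng = np.random.default_rng(6)
        rs = radial_sum(power_spectrum(rng.uniform(0, 1, (32, 32)), 1.0))
        sm = smooth_radial(rs)
        assert sm.s.sum() == pytest.approx(rs.s.sum(), rel=0.01)

    def test_binning_artifact_attenuated(self):
        """The quasi-periodic (period ~26.5 bins) binning structure must be
        suppressed by >= 10x at the default radius."""
        from l1agg.spectral import RadialSpectrum
        n = 1024
        x = np.arange(n, dtype=float)
        saw = (x / 26.5) % 1.0 - 0.5
        rs = RadialSpectrum(s=saw)
        sm = smooth_radial(rs)
        assert np.ptp(sm.s[100:-100]) < np.ptp(saw) / 10.0


class TestSyntheticPatternsEndToEnd:
    def test_square_lattice_peaks_at_inverse_spacing(self):
        img = synthetic_pattern(spacing_cm=0.125, spot_radius_cm=0.03,
                                lattice="square", n_px=256)
        rs = smooth_radial(radial_sum(power_spectrum(img, 1.0)))
        assert dominant_peak(rs) == pytest.approx(8.0, abs=0.5)

    def test_hex_lattice_first_ring(self):
        # reciprocal ring of hexagonal packing at 2/(sqrt(3)*a)
        a = 0.1
        img = synthetic_pattern(spacing_cm=a, spot_radius_cm=0.02,
                                lattice="hex", n_px=256)
        rs = smooth_radial(radial_sum(power_spectrum(img, 1.0)))
        assert dominant_peak(rs) == pytest.approx(2.0 / (math.sqrt(3) * a),
                                                  abs=1.0)

    def test_doubling_image_scale_halves_peak(self):
        img = synthetic_pattern(spacing_cm=0.125, spot_radius_cm=0.03,
                                lattice="square", n_px=256)
        rs1 = smooth_radial(radial_sum(power_spectrum(img, 1.0)))
        rs2 = smooth_radial(radial_sum(power_spectrum(img, 2.0)))
        assert dominant_peak(rs2) == pytest.approx(dominant_peak(rs1) / 2,
                                                   abs=0.25)

    def test_spot_count_matches_lattice_geometry(self):
        from scipy import ndimage
        a = 0.125
        img = synthetic_pattern(spacing_cm=a, spot_radius_cm=0.02,
                                lattice="square", n_px=256)
        _, n = ndimage.label(img > 0.5)
        assert n == pytest.approx(1.0 / a ** 2, rel=0.1)

    def test_jitter_broadens_but_keeps_peak_location(self):
        a = 0.1
        rs = {}
        for j in (0.0, 0.15):
            img = synthetic_pattern(spacing_cm=a, spot_radius_cm=0.015,
                                    lattice="hex", jitter=j, n_px=256, seed=7)
            rs[j] = smooth_radial(radial_sum(power_spectrum(img, 1.0)))
        p0, pj = dominant_peak(rs[0.0]), dominant_peak(rs[0.15])
        assert pj == pytest.approx(p0, abs=1.5)

        def fwhm(r):
            s = r.s.copy()
            s[r.k_cyc < 2.0] = 0.0
            half = s.max() / 2
            return np.count_nonzero(s > half)

        assert fwhm(rs[0.15]) > fwhm(rs[0.0])

    def test_pure_cosine_power_localized_in_radial_bins(self):
        """>= 95% of non-DC power within one bin width of the true mode."""
        m = 9
        img = 0.5 + 0.4 * np.cos(
            2 * np.pi * m * np.arange(128)[:, None] / 128) * np.ones((1, 128))
        rs = radial_sum(power_spectrum(img, 1.0))
        s = rs.s.copy()
        s[0] = 0.0                     # remove DC
        bin_w = 20.0 / 1023
        near = np.abs(rs.k_cyc - m) <= bin_w + 1e-9
        assert s[near].sum() >= 0.95 * s.sum()

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            synthetic_pattern(spacing_cm=0.02, spot_radius_cm=0.02)
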