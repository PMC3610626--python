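"""Per-STRF metric identities and invariances."""

import numpy as np
import pytest

from strflearn import strfmetrics


def embed_diag(values, shape=(50, 60)):
    p = np.zeros(shape)
    for i, v in enumerate(values):
        p[i, i] = v
    return p


class TestSeparability:
    def test_rank_one_is_zero(self, rng):
        p = np.outer(rng.standard_normal(50), rng.standard_normal(60))
        assert strfmetrics.separability_index(p) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_singular_values(self):
        assert strfmetrics.separability_index(embed_diag([1.0, 1.0])) == pytest.approx(0.5)

    def test_diag_two_one(self):
        # singular values (2, 1): spi = 1 - 4/5 = 0.2
        assert strfmetrics.separability_index(embed_diag([2.0, 1.0])) == pytest.approx(0.2)

    def test_transpose_and_scaling_invariance(self, rng):
        p = rng.standard_normal((50, 60))
        s = strfmetrics.separability_index(p)
        assert strfmetrics.separability_index(p.T) == pytest.approx(s)
        assert strfmetrics.separability_index(3.7 * p) == pytest.approx(s)

    def test_zero_patch_errors(self):
        with pytest.raises(ValueError):
            strfmetrics.separability_index(np.zeros((50, 60)))


class TestMTF:
    def test_constant_patch_warns_zero_mtf(self):
        with pytest.warns(UserWarning):
            mtf = strfmetrics.compute_mtf(np.ones((50, 60)))
        assert np.all(mtf.magnitude == 0)

    def test_ripple_single_dominant_peak(self, make_ripple_patch):
        mtf = strfmetrics.compute_mtf(make_ripple_patch(8.0, 0.5))
        i, j = np.unravel_index(np.argmax(mtf.magnitude), mtf.magnitude.shape)
        assert mtf.rates_hz[i] == pytest.approx(8.0)
        assert mtf.scales_cpo[j] == pytest.approx(0.5)
        # peak dominance over the median
        assert mtf.magnitude[i, j] > 20 * np.median(mtf.magnitude)

    def test_axes(self, make_ripple_patch):
        mtf = strfmetrics.compute_mtf(make_ripple_patch(8.0, 0.5))
        assert np.diff(mtf.rates_hz)[0] == pytest.approx(4.0)
        assert np.diff(mtf.scales_cpo)[0] == pytest.approx(1 / 6)
        assert mtf.rates_hz.min() == -96.0 and mtf.rates_hz.max() == 96.0
        assert mtf.scales_cpo.min() == 0.0

    def test_sign_flip_invariance(self, rng):
        p = rng.standard_normal((50, 60))
        m1 = strfmetrics.compute_mtf(p)
        m2 = strfmetrics.compute_mtf(-p)
        np.testing.assert_allclose(m1.magnitude, m2.magnitude, atol=1e-10)

    def test_parseval_energy(self, rng):
        """Total squared MTF magnitude (full plane) equals n*m times the
        thresholded-patch energy (Parseval)."""
        p = rng.standard_normal((50, 60))
        sd = p.std()
        thr = np.where(np.abs(p) > sd, p, 0.0)
        full = np.abs(np.fft.fft2(thr)) ** 2
        assert full.sum() == pytest.approx((thr**2).sum() * 50 * 60, rel=1e-10)
        # the retained half-plane (Nyquist bins dropped) carries >= ~half of it
        mtf = strfmetrics.compute_mtf(p)
        assert (mtf.magnitude**2).sum() <= full.sum()
        assert (mtf.magnitude**2).sum() >= 0.4 * full.sum()


class TestBestRateScale:
    @pytest.mark.parametrize("rate", [4.0, 12.0, 24.0, 48.0, 80.0])
    @pytest.mark.parametrize("scale", [1 / 6, 0.5, 1.0, 2.0, 4.0])
    def test_recovers_planted_ripple_grid(self, rate, scale, make_ripple_patch):
        mtf = strfmetrics.compute_mtf(make_ripple_patch(rate, scale))
        br, bs = strfmetrics.best_rate_scale(mtf)
        assert abs(br - rate) <= 4.0 + 1e-9
        assert abs(bs - scale) <= 1 / 6 + 1e-9

    def test_purely_temporal_patch_lowest_scale(self):
        p = np.tile(np.sin(2 * np.pi * 12 * np.arange(50) * 0.005)[:, None], (1, 60))
        br, bs = strfmetrics.best_rate_scale(strfmetrics.compute_mtf(p))
        assert bs == pytest.approx(0.0)
        assert br == pytest.approx(12.0, abs=4.0)

    def test_symmetric_double_peak_positive_br(self, make_ripple_patch):
        p = make_ripple_patch(12.0, 0.5, direction="down") + make_ripple_patch(12.0, 0.5, direction="up")
        br, _ = strfmetrics.best_rate_scale(strfmetrics.compute_mtf(p))
        assert br == pytest.approx(12.0, abs=4.0)

    def test_zero_mtf_undefined(self):
        with pytest.warns(UserWarning):
            mtf = strfmetrics.compute_mtf(np.ones((50, 60)))
            br, bs = strfmetrics.best_rate_scale(mtf)
        assert np.isnan(br) and np.isnan(bs)


class TestProfiles:
    def test_ripple_rate_profile_peak(self, make_ripple_patch):
        prof = strfmetrics.modulation_profiles(strfmetrics.compute_mtf(make_ripple_patch(10.0, 0.5)))
        peak_rate = prof.rate_axis_hz[np.argmax(prof.rate_profile)]
        assert 8.0 <= peak_rate <= 12.0

    def test_single_bin_profile_interpolated_cutoff(self):
        mtf = strfmetrics.ModulationTransferFunction(
            magnitude=np.zeros((5, 4)), rates_hz=np.array([-8.0, -4.0, 0.0, 4.0, 8.0]),
            scales_cpo=np.array([0.0, 1 / 6, 2 / 6, 3 / 6]),
        )
        mtf.magnitude[3, 1] = 1.0  # single bin at (4 Hz, 1/6 cpo)
        prof = strfmetrics.modulation_profiles(mtf)
        # profile = [0, 1, 0]; cutoff interpolates within (4, 8):
        level = 10 ** (-6 / 20)
        assert prof.rate_cutoff6db_hz == pytest.approx(4.0 + (1 - level) * 4.0)
        assert prof.scale_cutoff6db_cpo == pytest.approx((1 + (1 - level)) / 6)

    def test_flat_profile_cutoff_at_axis_max(self):
        mtf = strfmetrics.ModulationTransferFunction(
            magnitude=np.ones((5, 4)), rates_hz=np.array([-8.0, -4.0, 0.0, 4.0, 8.0]),
            scales_cpo=np.array([0.0, 1 / 6, 2 / 6, 3 / 6]),
        )
        with pytest.warns(UserWarning):
            prof = strfmetrics.modulation_profiles(mtf)
        assert prof.rate_cutoff6db_hz == pytest.approx(8.0)
        assert prof.scale_cutoff6db_cpo == pytest.approx(0.5)

    def test_profiles_normalized_to_peak_one(self, make_ripple_patch):
        prof = strfmetrics.modulation_profiles(strfmetrics.compute_mtf(make_ripple_patch(10.0, 1.0)))
        assert prof.rate_profile.max() == pytest.approx(1.0)
        assert prof.scale_profile.max() == pytest.approx(1.0)


class TestDirectionality:
    def test_separable_patch_exact_zero(self, rng):
        """A separable (time x frequency) patch has exactly quadrant-symmetric
        modulation energy, so DSI vanishes; computed on the unthresholded MTF
        since thresholding breaks separability."""
        p = np.outer(np.sin(np.arange(50) / 4), np.cos(np.arange(60) / 7))
        mtf = strfmetrics.compute_mtf(p, threshold_sd=0.0)
        assert abs(strfmetrics.directionality_index(mtf)) < 1e-10

    def test_separable_patch_small_after_thresholding(self):
        p = np.outer(np.sin(np.arange(50) / 4), np.cos(np.arange(60) / 7))
        assert abs(strfmetrics.directionality_index(strfmetrics.compute_mtf(p))) < 0.05

    @pytest.mark.parametrize("direction,sign", [("down", 1), ("up", -1)])
    def test_single_direction_ripple(self, direction, sign, make_ripple_patch):
        p = make_ripple_patch(8.0, 0.5, direction=direction)
        dsi = strfmetrics.directionality_index(strfmetrics.compute_mtf(p))
        assert abs(dsi) > 0.95
        assert np.sign(dsi) == sign

    def test_bounded(self, rng):
        for _ in range(10):
            p = rng.standard_normal((50, 60))
            dsi = strfmetrics.directionality_index(strfmetrics.compute_mtf(p))
            assert -1.0 <= dsi <= 1.0


class TestCompactness:
    def test_isotropic_blob_is_circle(self):
        ti, fi = np.indices((50, 60))
        blob = np.exp(-((ti - 25) ** 2 + (fi - 30) ** 2) / (2 * 6.0**2))
        assert strfmetrics.compactness(blob) == pytest.approx(1.0, abs=0.02)

    def test_elongated_blob_matches_ellipse_oracle(self):
        # 5:1 aspect: q = 4*pi*a*b / P(a,b)^2 with Ramanujan perimeter
        a, b = 5.0, 1.0
        P = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        q_expected = 4 * np.pi * (np.pi * a * b) / P**2
        ti, fi = np.indices((50, 60))
        blob = np.exp(-((ti - 25) ** 2 / (2 * 10.0**2) + (fi - 30) ** 2 / (2 * 2.0**2)))
        assert strfmetrics.compactness(blob) == pytest.approx(q_expected, abs=0.05)

    def test_bounded_unit_interval(self, rng):
        for _ in range(5):
            p = rng.standard_normal((50, 60))
            q = strfmetrics.compactness(p)
            if np.isfinite(q):
                assert 0 < q <= 1 + 1e-9

    def test_sign_flip_invariance(self):
        ti, fi = np.indices((50, 60))
        blob = np.exp(-((ti - 20) ** 2 / 40 + (fi - 35) ** 2 / 160))
        assert strfmetrics.compactness(-blob) == pytest.approx(strfmetrics.compactness(blob), rel=1e-6)


def test_compute_metrics_bundle(make_ripple_patch):
    m = strfmetrics.compute_metrics(make_ripple_patch(12.0, 0.5))
    assert 0 <= m.spi < 1
    assert m.br_hz == pytest.approx(12.0, abs=4.0)
    assert m.bs_cpo == pytest.approx(0.5, abs=1 / 6)
    assert -1 <= m.dsi <= 1
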