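"""Kinetic model, single-delay inversion, weighted-delay ATT, smoothing."""

import numpy as np
import pytest

from aslbs.quantify import (
    DEFAULT_PLDS,
    KineticParams,
    MultiDelaySeries,
    WeightedDelayInverter,
    att_from_wd,
    buxton_signal,
    cbf_from_multidelay,
    cbf_single_delay,
    fit_multidelay,
    gaussian_smooth,
    weighted_delay,
)

KP = KineticParams()


class TestBuxtonSignal:
    def test_zero_before_arrival(self):
        assert buxton_signal(500.0, 60.0, 1200.0, KP) == 0.0

    def test_continuity_at_bolus_end(self):
        att, tau = 800.0, KP.tau
        eps = 1e-7
        lo = buxton_signal(att + tau - eps, 60.0, att, KP)
        hi = buxton_signal(att + tau + eps, 60.0, att, KP)
        assert lo == pytest.approx(hi, abs=1e-12)

    def test_continuity_at_arrival(self):
        att = 1200.0
        assert buxton_signal(att + 1e-9, 60.0, att, KP) == pytest.approx(0.0, abs=1e-12)

    def test_single_delay_round_trip(self):
        """At att=0 the closed-form CBF equation inverts the kinetic model
        exactly."""
        tau, pld, f = KP.tau, 2200.0, 60.0
        dm = buxton_signal(tau + pld, f, 0.0, KP)
        assert cbf_single_delay(dm, 1.0, pld, KP) == pytest.approx(f, rel=1e-12)

    def test_peak_amplitude_subpercent(self):
        """Perfusion signal is under 1% of M0 at physiological CBF."""
        t = np.linspace(0, 6000, 601)
        sig = buxton_signal(t, 60.0, 1200.0, KP)
        assert 0.001 < sig.max() < 0.01


class TestSingleDelayCBF:
    def test_zero_dm_gives_zero(self):
        assert cbf_single_delay(0.0, 1.0, 2200.0, KP) == 0.0

    def test_alpha_scaling(self):
        kp2 = KineticParams(alpha=KP.alpha / 2)
        assert cbf_single_delay(0.005, 1.0, 2200.0, kp2) == pytest.approx(
            2 * cbf_single_delay(0.005, 1.0, 2200.0, KP), rel=1e-12
        )

    def test_invalid_m0_masked(self):
        out = cbf_single_delay(
            np.array([0.005, 0.005]),
            np.array([1.0, 0.0]),
            2200.0,
            KP,
            mask=np.array([True, False]),
        )
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestWeightedDelay:
    def test_equal_weights_give_mean(self):
        series = MultiDelaySeries(
            plds=(1275.0, 1800.0, 2100.0), dm=np.ones((3, 4)), m0=np.ones(4)
        )
        np.testing.assert_allclose(weighted_delay(series), 1725.0)

    def test_point_mass(self):
        dm = np.zeros((5, 1))
        dm[-1] = 1.0
        series = MultiDelaySeries(plds=DEFAULT_PLDS, dm=dm, m0=np.ones(1))
        assert weighted_delay(series)[0] == pytest.approx(2100.0)

    def test_matches_literal_sum_oracle(self):
        """WD for a kinetic-model voxel equals the direct sum evaluation,
        with the duplicate 100 ms delay entering twice."""
        f, att = 60.0, 1200.0
        dm = np.array(
            [buxton_signal(KP.tau + p, f, att, KP) for p in DEFAULT_PLDS]
        ).reshape(-1, 1)
        series = MultiDelaySeries(plds=DEFAULT_PLDS, dm=dm, m0=np.ones(1))
        oracle = sum(p * d for p, d in zip(DEFAULT_PLDS, dm[:, 0])) / sum(dm[:, 0])
        assert weighted_delay(series)[0] == pytest.approx(oracle, rel=1e-12)

    def test_nonpositive_sum_invalid(self):
        series = MultiDelaySeries(
            plds=(100.0, 1800.0), dm=np.array([[-1.0], [0.5]]), m0=np.ones(1)
        )
        assert np.isnan(weighted_delay(series)[0])


class TestAttInversion:
    def test_inverse_of_forward(self):
        inv = WeightedDelayInverter(DEFAULT_PLDS, KP)
        for att_true in (300.0, 800.0, 1200.0, 1700.0):
            dm = np.array(
                [buxton_signal(KP.tau + p, 60.0, att_true, KP) for p in DEFAULT_PLDS]
            ).reshape(-1, 1)
            wd = weighted_delay(
                MultiDelaySeries(plds=DEFAULT_PLDS, dm=dm, m0=np.ones(1))
            )
            att_hat, clamped = inv(wd)
            assert not clamped[0]
            assert att_hat[0] == pytest.approx(att_true, abs=10.0)

    def test_out_of_range_clamps_with_flag(self):
        inv = WeightedDelayInverter(DEFAULT_PLDS, KP)
        att_hat, clamped = inv(np.array([inv.wd_grid[0] - 50.0]))
        assert clamped[0]
        assert att_hat[0] == inv.att_grid[0]

    def test_wd_curve_monotone(self):
        inv = WeightedDelayInverter(DEFAULT_PLDS, KP)
        assert np.all(np.diff(inv.wd_grid) > 0)
        # the usable window covers the physiological ATT range
        assert inv.att_grid[0] <= 100.0
        assert inv.att_grid[-1] >= 2000.0


class TestMultiDelayCBF:
    def _voxel_series(self, f, att):
        dm = np.array(
            [buxton_signal(KP.tau + p, f, att, KP) for p in DEFAULT_PLDS]
        ).reshape(-1, 1)
        return MultiDelaySeries(plds=DEFAULT_PLDS, dm=dm, m0=np.ones(1))

    def test_noiseless_joint_recovery(self):
        for f, att in [(60.0, 600.0), (60.0, 1200.0), (20.0, 1600.0), (45.0, 1900.0)]:
            series = self._voxel_series(f, att)
            cbf, att_hat = fit_multidelay(series, KP)
            assert abs(att_hat[0] - att) <= 20.0
            assert abs(cbf[0] - f) / f <= 0.02

    def test_linearity_in_dm(self):
        series = self._voxel_series(60.0, 1200.0)
        scaled = MultiDelaySeries(plds=DEFAULT_PLDS, dm=3 * series.dm, m0=series.m0)
        f1 = cbf_from_multidelay(series, np.array([1200.0]), KP)
        f3 = cbf_from_multidelay(scaled, np.array([1200.0]), KP)
        assert f3[0] == pytest.approx(3 * f1[0], rel=1e-12)

    def test_att_beyond_all_readouts_invalid(self):
        series = self._voxel_series(60.0, 1200.0)
        f = cbf_from_multidelay(series, np.array([KP.tau + 2100.0 + 500.0]), KP)
        assert np.isnan(f[0])


class TestSmoothing:
    def test_constant_image_unchanged(self):
        img = 7.0 * np.ones((12, 12, 8))
        out = gaussian_smooth(img, (3.4, 3.4, 4.0), fwhm_mm=3.0)
        np.testing.assert_allclose(out, img, rtol=1e-10)

    def test_delta_fwhm_matches_request(self):
        """The impulse response measured along x has the requested FWHM
        (in mm) to within half a voxel."""
        vs = (1.0, 1.0, 1.0)
        img = np.zeros((41, 41, 41))
        img[20, 20, 20] = 1.0
        out = gaussian_smooth(img, vs, fwhm_mm=3.0)
        profile = out[:, 20, 20]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        fwhm_measured = above[-1] - above[0] + 1
        assert abs(fwhm_measured - 3.0) <= 1.0

    def test_interior_mass_preserved(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(1, 2, size=(24, 24, 16))
        out = gaussian_smooth(img, (3.4, 3.4, 4.0), fwhm_mm=3.0)
        inner = (slice(4, -4),) * 2 + (slice(2, -2),)
        assert np.sum(out[inner]) == pytest.approx(np.sum(img[inner]), rel=1e-2)

    def test_nan_voxels_do_not_bleed(self):
        img = np.ones((10, 10, 10))
        img[5, 5, 5] = np.nan
        out = gaussian_smooth(img, (1.0, 1.0, 1.0), fwhm_mm=3.0)
        assert np.isnan(out[5, 5, 5])
        ok = ~np.isnan(out)
        np.testing.assert_allclose(out[ok], 1.0, rtol=1e-9)
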