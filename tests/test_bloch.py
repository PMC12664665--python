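"""Longitudinal-magnetization model: closed form vs oracle, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aslbs.bloch import (
    BSSequenceTiming,
    MzState,
    PulseEfficiency,
    REFERENCE_RESIDUALS,
    REFERENCE_TIMINGS,
    TissueRelaxation,
    calibrate_efficiency,
    invert,
    mz_trajectory,
    relax,
    residual_mz,
)

SCHEMES = ("regular", "enhanced", "csf")
TISSUES = ("GM", "WM", "CSF")


def stepwise_residual(timing, t1, eff, dt=0.01):
    """Independent oracle: march Mz in small exact-decay steps, applying
    each inversion when its time is crossed."""
    events = sorted(timing.inversion_times)
    mz = 1.0 - eff.saturation_efficiency
    t = 0.0
    pending = list(events)
    while t < timing.readout_time - 1e-12:
        t_next = min(pending[0] if pending else np.inf, timing.readout_time, t + dt)
        mz = 1.0 - (1.0 - mz) * np.exp(-(t_next - t) / t1)
        t = t_next
        if pending and abs(t - pending[0]) < 1e-12:
            mz = -eff.inversion_efficiency * mz
            pending.pop(0)
    return mz


class TestPrimitives:
    def test_relax_examples(self):
        assert relax(MzState(0.0), 1800.0, 1209.0).mz == pytest.approx(
            1 - np.exp(-1800 / 1209), abs=1e-12
        )
        assert relax(MzState(0.0), 1800.0, 1209.0).mz == pytest.approx(0.7744, abs=1e-4)
        # equilibrium is a fixed point; long times recover fully
        assert relax(MzState(1.0), 123.0, 800.0).mz == pytest.approx(1.0)
        assert relax(MzState(0.0), 1e9, 1209.0).mz == pytest.approx(1.0)

    def test_invert_examples(self):
        assert invert(MzState(0.5), 1.0).mz == -0.5
        assert invert(MzState(0.8551), 0.93).mz == pytest.approx(-0.7952, abs=5e-5)
        assert invert(MzState(0.0), 0.9).mz == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            relax(MzState(0.0), 10.0, -1.0)
        with pytest.raises(ValueError):
            invert(MzState(0.5), 1.5)
        with pytest.raises(ValueError):
            TissueRelaxation(t1_gm=-5)
        with pytest.raises(ValueError):
            BSSequenceTiming(1800, 2200, (3585, 2336))  # unordered
        with pytest.raises(ValueError):
            BSSequenceTiming(1800, 2200, (500, 3585), constrained=True)

    @given(
        mz=st.floats(-1, 1),
        dt=st.floats(0, 1e4),
        t1=st.floats(100, 5000),
        eff=st.floats(0.5, 1.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_mz_stays_bounded(self, mz, dt, t1, eff):
        """|Mz| <= 1 is preserved by relaxation and inversion."""
        state = relax(MzState(mz), dt, t1)
        assert abs(state.mz) <= 1 + 1e-12
        assert abs(invert(state, eff).mz) <= 1 + 1e-12


class TestResidual:
    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("tissue", TISSUES)
    def test_matches_stepwise_oracle(self, scheme, tissue, t1s, eff,
                                     reference_timings):
        timing = reference_timings[scheme]
        t1 = t1s.as_dict()[tissue]
        closed = residual_mz(timing, t1, eff)
        oracle = stepwise_residual(timing, t1, eff)
        assert closed == pytest.approx(oracle, abs=1e-9)

    def test_reference_residuals_with_default_beta(self, t1s, eff,
                                                   reference_timings,
                                                   reference_residuals):
        """Default beta=0.93 reproduces the published residuals to ~0.06%."""
        for scheme, timing in reference_timings.items():
            for tissue, t1 in t1s.as_dict().items():
                sim = 100.0 * residual_mz(timing, t1, eff)
                assert sim == pytest.approx(
                    reference_residuals[scheme][tissue], abs=0.1
                )

    def test_pure_saturation_recovery(self, eff):
        timing = BSSequenceTiming(1800.0, 2200.0, ())
        assert residual_mz(timing, 1209.0, eff) == pytest.approx(
            1 - np.exp(-4000 / 1209), abs=1e-12
        )

    def test_monotone_in_readout_without_inversions(self, eff):
        residuals = [
            residual_mz(BSSequenceTiming(1800.0, pld, ()), 1209.0, eff)
            for pld in (200.0, 800.0, 1400.0, 2200.0)
        ]
        assert np.all(np.diff(residuals) > 0)

    def test_even_inversions_positive_after_full_recovery(self):
        """With perfect pulses and both TIs late enough for near-complete
        recovery, two inversions leave the sign positive."""
        eff = PulseEfficiency(inversion_efficiency=1.0)
        timing = BSSequenceTiming(10000.0, 10000.0, (9000.0, 19000.0))
        assert residual_mz(timing, 400.0, eff) > 0


class TestTrajectory:
    def test_endpoint_equals_residual(self, t1s, eff, reference_timings):
        timing = reference_timings["csf"]
        curve = mz_trajectory(timing, t1s.t1_csf, eff, step=5.0)
        assert curve[-1, 0] == timing.readout_time
        assert curve[-1, 1] == pytest.approx(
            residual_mz(timing, t1s.t1_csf, eff), abs=1e-12
        )
        assert curve[-1, 1] == pytest.approx(-0.002, abs=5e-4)

    def test_coarse_step_degenerates_to_segment_knots(self, eff):
        timing = BSSequenceTiming(1800.0, 2200.0, ())
        curve = mz_trajectory(timing, 1209.0, eff, step=1e6)
        assert curve.shape[0] == 2  # start and readout only

    def test_endpoint_signs_match_reference_table(self, t1s, eff,
                                                  reference_timings,
                                                  reference_residuals):
        for scheme, timing in reference_timings.items():
            for tissue, t1 in t1s.as_dict().items():
                curve = mz_trajectory(timing, t1, eff, step=10.0)
                assert np.sign(curve[-1, 1]) == np.sign(
                    reference_residuals[scheme][tissue]
                )

    def test_discontinuities_only_at_inversion_times(self, t1s, eff,
                                                     reference_timings):
        timing = reference_timings["regular"]
        curve = mz_trajectory(timing, t1s.t1_gm, eff, step=1.0)
        jumps = np.abs(np.diff(curve[:, 1]))
        jump_times = curve[1:, 0][jumps > 0.05]
        assert set(np.round(jump_times)) <= set(
            np.round(timing.inversion_times)
        )


class TestCalibration:
    def test_recovers_reference_efficiency(self, t1s, reference_timings,
                                           reference_residuals):
        """Calibration on the nine published residuals lands at beta~0.93,
        and at the calibrated beta every cell round-matches."""
        timings = [reference_timings[s] for s in SCHEMES]
        observed = [reference_residuals[s] for s in SCHEMES]
        beta = calibrate_efficiency(timings, observed, t1s)
        assert beta == pytest.approx(0.93, abs=0.005)
        eff = PulseEfficiency(inversion_efficiency=beta)
        for scheme, timing in reference_timings.items():
            for tissue, t1 in t1s.as_dict().items():
                sim = round(100.0 * residual_mz(timing, t1, eff), 1)
                assert sim == reference_residuals[scheme][tissue]

    @pytest.mark.parametrize("true_beta", [0.9, 1.0])
    def test_self_consistency(self, true_beta, t1s, reference_timings):
        """Residuals generated at a known beta are recovered exactly."""
        timings = [reference_timings[s] for s in SCHEMES]
        gen = PulseEfficiency(inversion_efficiency=true_beta)
        observed = [
            {
                tissue: 100.0 * residual_mz(timing, t1, gen)
                for tissue, t1 in t1s.as_dict().items()
            }
            for timing in timings
        ]
        assert calibrate_efficiency(timings, observed, t1s) == pytest.approx(
            true_beta, abs=1e-4
        )

    def test_empty_table_rejected(self, t1s):
        with pytest.raises(ValueError):
            calibrate_efficiency([], [], t1s)
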