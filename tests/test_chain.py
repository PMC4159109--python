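"""Analog monitoring chain, calibration mapping, and controller logic."""

import numpy as np
import pytest

from cavmon.chain import (
    CalibrationTable,
    ChainConfig,
    ControllerConfig,
    ControllerState,
    analog_chain,
    controller_step,
    derive_threshold,
    rms_envelope,
    run_closed_loop,
    scheduled_ramp_step,
)
from cavmon.spectral import PCDRecord
from cavmon.synth import SyntheticConfig

FS = 10e6


def _tone(freq, amp, duration=0.02, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return PCDRecord(amp * np.sin(2 * np.pi * freq * t), fs)


class TestAnalogChain:
    def test_zero_in_zero_out(self):
        env = analog_chain(_tone(1.65e6, 0.0))
        assert np.all(env == 0)

    def test_rectified_tone_mean_is_a_gain_over_pi(self):
        # half-wave rectified sinusoid of amplitude A has mean A/pi
        amp, gain = 2e-5, 20_000.0
        chain = ChainConfig(preamp_gain=gain, highpass_cutoff=None)
        env = analog_chain(_tone(1.65e6, amp, duration=0.05), chain)
        settled = env[env.size // 5:]  # discard demodulator start-up
        assert np.mean(settled) == pytest.approx(amp * gain / np.pi, rel=0.01)

    def test_out_of_band_tone_strongly_rejected(self):
        in_band = rms_envelope(analog_chain(_tone(1.65e6, 1e-5)))
        out_band = rms_envelope(analog_chain(_tone(0.5e6, 1e-5)))
        assert out_band < 0.01 * in_band

    def test_output_rate_is_adc_rate(self):
        chain = ChainConfig()
        env = analog_chain(_tone(1.65e6, 1e-5, duration=0.05), chain)
        assert env.size == pytest.approx(0.05 * chain.adc_rate, rel=0.01)

    def test_nyquist_violation_rejected(self):
        rec = PCDRecord(np.zeros(1000), sampling_rate=3.0e6)
        with pytest.raises(ValueError):
            analog_chain(rec)


class TestRMSEnvelope:
    def test_constant(self):
        assert rms_envelope(np.full(100, 3.7)) == pytest.approx(3.7)

    def test_two_samples(self):
        assert rms_envelope([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_sinusoid_about_mean(self):
        m, a = 2.0, 0.5
        t = np.linspace(0, 1, 100_000, endpoint=False)
        x = m + a * np.sin(2 * np.pi * 10 * t)
        assert rms_envelope(x) == pytest.approx(np.sqrt(m**2 + a**2 / 2), rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_envelope([])


class TestDeriveThreshold:
    def test_noise_subtraction_arithmetic(self):
        # corner lands at 0.09, minus 1.5 x 0.02 -> 0.06 (the deployed value)
        scores = np.array([0.01, 0.02, 0.03, 0.09, 0.10, 0.12])
        labels = np.array([False, False, False, True, True, True])
        assert derive_threshold(scores, labels, noise_rms=0.02) == pytest.approx(0.06)
        assert derive_threshold(scores, labels, noise_rms=0.0) == pytest.approx(0.09)

    def test_floor_at_zero(self):
        scores = np.array([0.01, 0.02, 0.05, 0.06])
        labels = np.array([False, False, True, True])
        assert derive_threshold(scores, labels, noise_rms=1.0) == 0.0

    def test_adjusted_never_exceeds_corner(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = rng.random(n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            noise = float(rng.random() * 0.2)
            adj = derive_threshold(scores, labels, noise)
            corner = derive_threshold(scores, labels, 0.0)
            assert adj <= corner + 1e-15


@pytest.fixture(scope="module")
def table():
    return CalibrationTable.default()


class TestCalibrationTable:

    @pytest.mark.parametrize(
        "mvpp,power,intensity",
        [(250, 20.28, 15690), (300, 28.42, 21980), (325, 32.06, 24430)],
    )
    def test_tabulated_rows_exact(self, table, mvpp, power, intensity):
        p, i = table.lookup(mvpp)
        assert p == pytest.approx(power)
        assert i == pytest.approx(intensity)

    def test_linear_interpolation_midpoint(self, table):
        p, _ = table.lookup(312.5)
        assert p == pytest.approx((28.42 + 32.06) / 2)  # 30.24 W

    def test_quadratic_extrapolation_below_table(self, table):
        p, i = table.lookup(125.0)
        assert p == pytest.approx(20.28 / 4)
        assert i == pytest.approx(15690 / 4)

    def test_start_intensity_voltage(self, table):
        v = table.voltage_for_intensity(9117.0)
        assert v == pytest.approx(250 * np.sqrt(9117 / 15690), rel=1e-9)  # ~190.6
        _, i = table.lookup(v)
        assert i == pytest.approx(9117.0)

    def test_above_maximum_rejected(self, table):
        with pytest.raises(ValueError):
            table.lookup(326.0)


class TestControllerStep:
    def test_above_threshold_steps_down(self, table):
        cfg = ControllerConfig()
        st = ControllerState(awg_voltage=250.0, below_count=4)
        action = controller_step(st, 0.10, cfg, table)
        assert action == "down"
        assert st.awg_voltage == 240.0
        assert st.below_count == 0

    def test_ten_consecutive_below_steps_up(self, table):
        cfg = ControllerConfig()
        st = ControllerState(awg_voltage=250.0, below_count=9)
        action = controller_step(st, 0.01, cfg, table)
        assert action == "up"
        assert st.awg_voltage == 260.0
        assert st.below_count == 0

    def test_clamped_at_max_intensity(self, table):
        cfg = ControllerConfig(max_intensity=21_980.0)
        st = ControllerState(awg_voltage=300.0, below_count=9)
        controller_step(st, 0.01, cfg, table)
        assert st.awg_voltage == 300.0  # 300 mVpp maps to the 21,980 cap

    def test_voltage_floor_at_zero(self, table):
        cfg = ControllerConfig()
        st = ControllerState(awg_voltage=5.0)
        controller_step(st, 0.10, cfg, table)
        assert st.awg_voltage == 0.0

    def test_inactive_ramp_is_monotone(self, table):
        cfg = ControllerConfig(active=False)
        st = ControllerState(awg_voltage=190.0)
        history = []
        for _ in range(120):
            scheduled_ramp_step(st, cfg, table)
            history.append(st.awg_voltage)
        assert np.all(np.diff(history) >= 0)
        assert history[-1] == pytest.approx(300.0)


class TestClosedLoop:
    def _no_hazard(self, n_cycles=30):
        return SyntheticConfig.desk(record_duration=0.002, hazard_scale=50.0,
                                    max_cycles=n_cycles)

    def test_infinite_threshold_matches_inactive_schedule(self):
        synth = self._no_hazard()
        chain = ChainConfig()
        kw = dict(max_cycles=30)
        ra = run_closed_loop(ControllerConfig(threshold=np.inf, active=True, **kw),
                             chain, synth, seed=2)
        ri = run_closed_loop(ControllerConfig(active=False, **kw), chain, synth, seed=2)
        np.testing.assert_array_equal(ra.log["voltage_mvpp"], ri.log["voltage_mvpp"])
        np.testing.assert_array_equal(ra.log["isptp_wcm2"], ri.log["isptp_wcm2"])

    def test_inactive_intensity_monotone_and_censored(self):
        synth = self._no_hazard(40)
        res = run_closed_loop(ControllerConfig(active=False, max_cycles=40),
                              ChainConfig(), synth, seed=1)
        assert not res.ruptured
        assert res.time_to_rupture == 40.0
        assert np.all(np.diff(res.log["isptp_wcm2"]) >= 0)

    def test_intensity_never_exceeds_cap(self):
        synth = self._no_hazard(60)
        res = run_closed_loop(ControllerConfig(active=True, max_cycles=60),
                              ChainConfig(), synth, seed=3)
        assert res.log["isptp_wcm2"].max() <= 21_980.0 + 1e-9

    def test_energy_is_duty_cycle_riemann_sum(self):
        synth = self._no_hazard(40)
        res = run_closed_loop(ControllerConfig(active=False, max_cycles=40),
                              ChainConfig(), synth, seed=4)
        expected = res.log["power_w"].sum() * 0.5
        assert res.total_acoustic_energy == pytest.approx(expected, rel=1e-9)

    def test_constant_power_energy_arithmetic(self):
        # 28.42 W for 100 cycles at 50% duty -> 1,421 J
        assert 28.42 * 0.5 * 100 == pytest.approx(1421.0)
        synth = self._no_hazard(100)
        cfg = ControllerConfig(active=False, max_cycles=100,
                               start_intensity=21_980.0, max_intensity=21_980.0)
        res = run_closed_loop(cfg, ChainConfig(), synth, seed=5)
        assert res.total_acoustic_energy == pytest.approx(1421.0, rel=1e-9)
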