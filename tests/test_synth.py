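"""Synthetic trial generator: determinism, amplitude model, hazard, flow."""

import numpy as np
import pytest

from cavmon.spectral import averaged_power_spectrum, band_energy, DEFAULT_BANDS
from cavmon.synth import (
    EMISSION_CLASSES,
    SyntheticConfig,
    VesselState,
    class_amplitudes,
    constant_schedule,
    generate_flow_trace,
    generate_pcd_record,
    generate_trial,
    update_vessel,
)

ZERO = {c: 0.0 for c in EMISSION_CLASSES}


def _silent(config, **kw):
    params = dict(band_base_amplitudes=dict(ZERO), growth_rates=dict(ZERO),
                  initial_burst_amplitude=0.0, noise_floor_rms=0.0)
    params.update(kw)
    return config.with_(**params)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"sampling_rate": 3.0e6},  # below subharmonic Nyquist
            {"record_duration": 0.0501234567},  # non-integer sample count
            {"flow_fluctuation": 0.05},  # would false-trigger detection
            {"noise_floor_rms": -1e-6},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig.desk(**kw)

    def test_desk_scale_above_nyquist(self, desk_config):
        assert desk_config.sampling_rate > 2 * 1.65e6
        assert desk_config.record_samples == 200_000


class TestGeneratePCDRecord:
    def test_noise_only_rms(self):
        cfg = _silent(SyntheticConfig.desk(), noise_floor_rms=0.01)
        rec = generate_pcd_record(cfg, 0, 0.0, np.random.default_rng(7))
        assert rec.samples.size >= 1e5
        assert np.sqrt(np.mean(rec.samples**2)) == pytest.approx(0.01, rel=0.01)

    def test_same_seed_bit_identical(self, desk_config):
        a = generate_pcd_record(desk_config, 3, 21980, np.random.default_rng(42))
        b = generate_pcd_record(desk_config, 3, 21980, np.random.default_rng(42))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_subharmonic_power_quadratic_in_amplitude(self, desk_config):
        # doubling the tone amplitude adds 6.02 dB of single-bin band power
        out = []
        for amp in (2e-6, 4e-6):
            cfg = _silent(desk_config)
            cfg = cfg.with_(band_base_amplitudes={**ZERO, "subharmonic": amp})
            rec = generate_pcd_record(cfg, 0, cfg.intensity_reference,
                                      np.random.default_rng(0))
            spec = averaged_power_spectrum(rec, 2000)
            out.append(band_energy(spec, DEFAULT_BANDS[2]))
        assert 10 * np.log10(out[1] / out[0]) == pytest.approx(6.02, abs=0.01)

    def test_amplitudes_monotone_in_time_and_intensity(self, desk_config):
        for c in EMISSION_CLASSES:
            s0, _ = class_amplitudes(desk_config, 10.0, 20000.0)
            s1, _ = class_amplitudes(desk_config, 60.0, 20000.0)
            s2, _ = class_amplitudes(desk_config, 60.0, 24000.0)
            assert s0[c] <= s1[c] <= s2[c]

    def test_negative_cycle_rejected(self, desk_config):
        with pytest.raises(ValueError):
            generate_pcd_record(desk_config, -1, 100.0, np.random.default_rng(0))

    def test_zero_amplitudes_give_zero_db_band_snr(self, desk_config):
        # noise-only records vs noise reference: 0 dB within sampling error;
        # 0.5-s records give 1,000 averaged segments, so even the single-bin
        # subharmonic ratio estimate sits well inside the +-0.5 dB band
        from cavmon.spectral import emission_time_series

        cfg = _silent(desk_config, noise_floor_rms=1e-5, record_duration=0.5)
        rng = np.random.default_rng(21)
        recs = [generate_pcd_record(cfg, i, 0.0, rng) for i in range(3)]
        ref = generate_pcd_record(cfg, 0, 0.0, rng)
        levels = emission_time_series(recs, ref)
        for band in EMISSION_CLASSES:
            assert np.max(np.abs(levels.snr_db(band))) < 0.5


class TestVesselModel:
    def test_zero_amplitudes_never_rupture(self, desk_config):
        rng = np.random.default_rng(0)
        state = VesselState()
        for _ in range(1000):
            update_vessel(state, ZERO, 1.0, rng, desk_config)
        assert not state.ruptured

    def test_constant_increment_ruptures_at_ceiling(self, desk_config):
        rng = np.random.default_rng(1)
        state = VesselState()
        state.threshold = 1.0
        c = 0.3
        for _ in range(100):
            update_vessel(state, {"subharmonic": c, "broadband": 0.0}, 1.0, rng, desk_config)
            if state.ruptured:
                break
        assert state.rupture_instant == np.ceil(1.0 / c)

    def test_rupture_time_quartiles_and_hazard_monotonicity(self, desk_config):
        # dose-only Monte Carlo: default-intensity amplitude trajectories
        def rupture_times(cfg, n=200):
            times = []
            for s in range(n):
                rng = np.random.default_rng(5000 + s)
                state = VesselState()
                intensity = [15690, 20570, 21350, 21980, 24430][s % 5]
                for t in range(300):
                    sustained, _ = class_amplitudes(cfg, float(t), intensity)
                    update_vessel(state, sustained, 1.0, rng, cfg)
                    if state.ruptured:
                        break
                times.append(state.rupture_instant or 300)
            return np.array(times)

        t_default = rupture_times(desk_config)
        q1, q3 = np.percentile(t_default, [25, 75])
        assert 5 <= q1 and q3 <= 300
        smaller = desk_config.with_(hazard_scale=desk_config.hazard_scale - 1.0)
        assert np.median(rupture_times(smaller)) < np.median(t_default)


class TestFlowTrace:
    def test_no_rupture_stays_above_drop(self, desk_config):
        for s in range(20):
            trace = generate_flow_trace(None, desk_config, np.random.default_rng(s))
            assert trace.current.min() > 0.97 * desk_config.flow_baseline

    def test_crossing_exactly_at_lag(self, desk_config):
        trace = generate_flow_trace(42.0, desk_config, np.random.default_rng(0))
        below = trace.time[trace.current < 0.97 * desk_config.flow_baseline]
        assert below[0] == 50.0

    def test_rupture_outside_duration_rejected(self, desk_config):
        with pytest.raises(ValueError):
            generate_flow_trace(500.0, desk_config, np.random.default_rng(0), duration=300)


class TestGenerateTrial:
    def test_hazard_disabled_runs_full_schedule(self, tiny_config):
        cfg = tiny_config.with_(hazard_scale=50.0)  # threshold astronomically high
        trial = generate_trial(cfg, constant_schedule(21980, 40), seed=3)
        assert len(trial.records) == 40
        assert trial.true_rupture_instant is None

    def test_same_seed_identical_trials(self, tiny_config):
        a = generate_trial(tiny_config, constant_schedule(21980, 60), seed=11)
        b = generate_trial(tiny_config, constant_schedule(21980, 60), seed=11)
        assert a.true_rupture_instant == b.true_rupture_instant
        assert len(a.records) == len(b.records)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.samples, rb.samples)
        np.testing.assert_array_equal(a.flow_trace.current, b.flow_trace.current)

    def test_no_records_after_rupture(self, tiny_config):
        trial = generate_trial(tiny_config, constant_schedule(24430, 300), seed=5)
        if trial.true_rupture_instant is not None:
            assert len(trial.records) == int(trial.true_rupture_instant)
            assert all(r.cycle_index < trial.true_rupture_instant for r in trial.records)

    def test_higher_intensity_shortens_rupture_paired(self, tiny_config):
        lo, hi = [], []
        for s in range(40):
            t_lo = generate_trial(tiny_config, constant_schedule(15690, 300), seed=7000 + s)
            t_hi = generate_trial(tiny_config, constant_schedule(24430, 300), seed=7000 + s)
            lo.append(t_lo.true_rupture_instant or 300)
            hi.append(t_hi.true_rupture_instant or 300)
        assert np.mean(hi) < np.mean(lo)

    def test_overlong_schedule_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            generate_trial(tiny_config, constant_schedule(20000, 301), seed=0)
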