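"""Analog monitoring chain, drive calibration, and the feedback controller.

The rupture-suppression experiments replace offline spectral analysis with
an analog chain: the PCD signal is bandpass-filtered around the 1.65-MHz
subharmonic, amplified (gain 20,000), half-wave rectified, smoothed by a
1,063-Hz AM demodulator (classic envelope detector), and digitized at
68.6 kHz; the RMS of the envelope over each 0.5-s insonation is the
controller's input.

The controller (one decision per 1-s cycle) compares that RMS to a fixed
threshold: above threshold it steps the function-generator drive down by
10 mVpp; after ten consecutive below-threshold cycles it steps the drive up,
clamped so the mapped focal intensity never exceeds the configured maximum.
The drive-voltage → acoustic-power → SPTP-intensity mapping is a measured
calibration table, linearly interpolated between rows and extrapolated
below the lowest row with the small-signal law power ∝ voltage².

The controller threshold itself is derived the way it was in the original
experiments: labeled emission records are pushed through a software model
of the analog chain, the ROC corner threshold of the resulting RMS values
is found, and 1.5 × the RMS noise level is subtracted for conservatism
(deployed value: 0.06 V_RMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .roc import corner_threshold, roc_curve
from .spectral import PCDRecord
from .synth import (
    EMISSION_CLASSES,
    SUBHARMONIC_HZ,
    SyntheticConfig,
    VesselState,
    class_amplitudes,
    generate_pcd_record,
    update_vessel,
)

__all__ = [
    "ChainConfig",
    "CalibrationTable",
    "ControllerConfig",
    "ControllerState",
    "ControlledTrialResult",
    "analog_chain",
    "rms_envelope",
    "derive_threshold",
    "controller_step",
    "scheduled_ramp_step",
    "run_closed_loop",
]


@dataclass(frozen=True)
class ChainConfig:
    """Transfer-function model of the subharmonic monitoring electronics."""

    bandpass_center: float = SUBHARMONIC_HZ  # Hz
    bandpass_fractional_bw: float = 0.10
    bandpass_order: int = 2
    preamp_gain: float = 20_000.0  # suppression chain; prediction chain used 100
    highpass_cutoff: float | None = 10e3  # Hz, 12 dB/octave (2nd order)
    demod_cutoff: float = 1_063.0  # Hz, 1st-order envelope low-pass
    adc_rate: float = 68.6e3  # Hz

    def __post_init__(self):
        if self.preamp_gain <= 0:
            raise ValueError("gain must be positive")
        if not 0 < self.bandpass_fractional_bw < 2:
            raise ValueError("fractional bandwidth must be in (0, 2)")


@lru_cache(maxsize=64)
def _design(order: int, freqs, btype: str, fs: float) -> np.ndarray:
    return sps.butter(order, freqs, btype=btype, fs=fs, output="sos")


def analog_chain(record: PCDRecord, chain: ChainConfig = ChainConfig()) -> np.ndarray:
    """Envelope samples at the ADC rate for one PCD record.

    Stages: zero-phase Butterworth bandpass at the subharmonic, preamp
    high-pass (12 dB/octave) and gain, half-wave rectification
    ``max(x, 0)``, causal first-order low-pass at the demodulator cutoff,
    then linear-interpolation resampling onto the ADC clock.
    """
    fs = record.sampling_rate
    if fs <= 2 * chain.bandpass_center:
        raise ValueError("record sampling rate must exceed twice the bandpass center")
    half_bw = 0.5 * chain.bandpass_fractional_bw * chain.bandpass_center
    sos = _design(
        chain.bandpass_order,
        (chain.bandpass_center - half_bw, chain.bandpass_center + half_bw),
        "bandpass",
        fs,
    )
    x = sps.sosfiltfilt(sos, record.samples)
    if chain.highpass_cutoff:
        x = sps.sosfilt(_design(2, chain.highpass_cutoff, "highpass", fs), x)
    x = chain.preamp_gain * x
    x = np.maximum(x, 0.0)
    env = sps.sosfilt(_design(1, chain.demod_cutoff, "lowpass", fs), x)
    t_in = np.arange(env.size) / fs
    t_adc = np.arange(0.0, t_in[-1], 1.0 / chain.adc_rate)
    return np.interp(t_adc, t_in, env)


def rms_envelope(envelope) -> float:
    """Root-mean-square of envelope samples over the on-period."""
    env = np.asarray(envelope, dtype=np.float64)
    if env.size == 0:
        raise ValueError("empty envelope")
    return float(np.sqrt(np.mean(env**2)))


def derive_threshold(rms_values, labels, noise_rms: float, k: float = 1.5) -> float:
    """Controller threshold: ROC corner on RMS scores minus k × noise RMS.

    ``labels`` mark pre-rupture cycles positive.  The corner threshold
    jointly maximizes sensitivity and specificity; subtracting
    ``k * noise_rms`` biases the controller toward earlier intervention.
    Floored at zero.
    """
    roc = roc_curve(rms_values, labels)
    report = corner_threshold(roc, rms_values, labels)
    return max(report.threshold - k * noise_rms, 0.0)


class CalibrationTable:
    """Drive voltage → acoustic power → SPTP focal intensity mapping.

    Rows are measured (voltage mVpp, power W, intensity W/cm², peak
    negative pressure MPa) conditions.  Between rows: linear interpolation
    in voltage.  Below the lowest row: quadratic (small-signal) extrapolation
    ``P ∝ V²`` anchored at the lowest row.  Above the highest row: error.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"awg_mvpp", "power_w", "isptp_wcm2"}
        if not required <= set(frame.columns):
            raise ValueError(f"calibration table needs columns {sorted(required)}")
        frame = frame.sort_values("awg_mvpp").reset_index(drop=True)
        v = frame["awg_mvpp"].to_numpy(dtype=np.float64)
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if np.any(np.diff(frame["power_w"].to_numpy()) < 0) or np.any(
            np.diff(frame["isptp_wcm2"].to_numpy()) < 0
        ):
            raise ValueError("power and intensity must be non-decreasing in voltage")
        self.frame = frame
        self._v = v
        self._p = frame["power_w"].to_numpy(dtype=np.float64)
        self._i = frame["isptp_wcm2"].to_numpy(dtype=np.float64)

    @classmethod
    def default(cls) -> "CalibrationTable":
        from .io import load_table_fixture

        return cls(load_table_fixture("calibration"))

    @property
    def v_min(self) -> float:
        return float(self._v[0])

    @property
    def v_max(self) -> float:
        return float(self._v[-1])

    def lookup(self, awg_voltage: float) -> tuple[float, float]:
        """(acoustic power W, SPTP intensity W/cm²) at a drive voltage."""
        if awg_voltage < 0:
            raise ValueError("voltage must be non-negative")
        if awg_voltage > self.v_max:
            raise ValueError(
                f"voltage {awg_voltage} mVpp above calibrated maximum {self.v_max}"
            )
        if awg_voltage < self.v_min:
            q = (awg_voltage / self.v_min) ** 2
            return float(self._p[0] * q), float(self._i[0] * q)
        return (
            float(np.interp(awg_voltage, self._v, self._p)),
            float(np.interp(awg_voltage, self._v, self._i)),
        )

    def voltage_for_intensity(self, intensity: float) -> float:
        """Inverse mapping, using the same quadratic law below the table."""
        if intensity < 0:
            raise ValueError("intensity must be non-negative")
        if intensity > self._i[-1]:
            raise ValueError("intensity above calibrated maximum")
        if intensity < self._i[0]:
            return float(self._v[0] * np.sqrt(intensity / self._i[0]))
        return float(np.interp(intensity, self._i, self._v))


@dataclass
class ControllerConfig:
    """Feedback-loop parameters.

    ``start_intensity`` 9,117 W/cm² and ``max_intensity`` 21,980 W/cm² are
    the deployed protocol values (the flow-diagram caption allows a
    24,430 W/cm² cap, configurable here).  ``threshold`` is in volts RMS at
    the demodulator output.
    """

    threshold: float = 0.06  # V_RMS
    decrease_step: float = 10.0  # mVpp
    increase_step: float = 10.0  # mVpp
    consecutive_required: int = 10
    start_intensity: float = 9_117.0  # W/cm^2
    max_intensity: float = 21_980.0  # W/cm^2
    max_cycles: int = 300
    active: bool = True

    def __post_init__(self):
        if self.decrease_step <= 0 or self.increase_step <= 0:
            raise ValueError("voltage steps must be positive")
        if self.start_intensity > self.max_intensity:
            raise ValueError("start intensity must not exceed the maximum")


@dataclass
class ControllerState:
    cycle: int = 0
    awg_voltage: float = 0.0  # mVpp
    below_count: int = 0
    intensity_history: list = field(default_factory=list)
    rms_history: list = field(default_factory=list)


def _max_voltage(config: ControllerConfig, table: CalibrationTable) -> float:
    return table.voltage_for_intensity(config.max_intensity)


def controller_step(
    state: ControllerState,
    rms: float,
    config: ControllerConfig,
    table: CalibrationTable,
) -> str:
    """Apply one feedback decision in place; returns the action taken.

    Above threshold: step the drive down and reset the counter.  Otherwise
    count; at ten consecutive below-threshold cycles step the drive up
    (clamped so the mapped intensity stays within ``max_intensity``) and
    reset.  Voltage never goes below zero.
    """
    if not config.active:
        raise ValueError("controller_step requires an active controller")
    if rms > config.threshold:
        state.awg_voltage = max(state.awg_voltage - config.decrease_step, 0.0)
        state.below_count = 0
        return "down"
    state.below_count += 1
    if state.below_count >= config.consecutive_required:
        v_cap = _max_voltage(config, table)
        state.awg_voltage = min(state.awg_voltage + config.increase_step, v_cap)
        state.below_count = 0
        return "up"
    return "hold"


def scheduled_ramp_step(
    state: ControllerState,
    config: ControllerConfig,
    table: CalibrationTable,
) -> str:
    """Controller-inactive drive schedule: monotone stepwise ramp to the cap.

    Uses the same cadence as the active loop's increase rule (one step per
    ``consecutive_required`` cycles) so active and inactive exposures are
    identical whenever the active threshold is never reached.
    """
    state.below_count += 1
    if state.below_count >= config.consecutive_required:
        v_cap = _max_voltage(config, table)
        state.awg_voltage = min(state.awg_voltage + config.increase_step, v_cap)
        state.below_count = 0
        return "up"
    return "hold"


@dataclass
class ControlledTrialResult:
    time_to_rupture: float  # s; censored trials report the full exposure time
    ruptured: bool
    mean_sptp_intensity: float  # W/cm^2
    total_acoustic_energy: float  # J
    log: pd.DataFrame  # per-cycle: cycle, voltage_mvpp, power_w, isptp_wcm2, rms_v, action


def run_closed_loop(
    config: ControllerConfig,
    chain: ChainConfig,
    synth: SyntheticConfig,
    seed: int,
    table: CalibrationTable | None = None,
    vessel_seed: int | None = None,
) -> ControlledTrialResult:
    """Run one feedback-controlled (or ramp-only) exposure against the
    synthetic vessel model.

    Per 1-s cycle: map drive voltage to power/intensity, synthesize the PCD
    record, push it through the analog chain, compute the envelope RMS,
    apply the controller (or the inactive ramp), and accumulate vessel
    dose.  Stops at rupture or ``max_cycles``.  ``vessel_seed`` seeds the
    rupture-threshold draw separately, so paired active/inactive trials can
    share the same latent vessel.
    """
    if table is None:
        table = CalibrationTable.default()
    rng = np.random.default_rng(seed)
    vessel_rng = np.random.default_rng(seed if vessel_seed is None else vessel_seed)

    state = ControllerState(awg_voltage=table.voltage_for_intensity(config.start_intensity))
    vessel = VesselState()
    # Per-vessel growth factor, drawn from the vessel stream so that paired
    # active/inactive trials share the same latent vessel.
    growth_factor = float(np.exp(synth.growth_heterogeneity * vessel_rng.standard_normal()))
    synth = synth.with_(
        growth_rates={c: g * growth_factor for c, g in synth.growth_rates.items()}
    )
    rows = []
    powers, intensities = [], []

    for cycle in range(config.max_cycles):
        power_w, intensity = table.lookup(state.awg_voltage)
        record = generate_pcd_record(synth, cycle, intensity, rng)
        env = analog_chain(record, chain)
        rms = rms_envelope(env)
        voltage_before = state.awg_voltage
        if config.active:
            action = controller_step(state, rms, config, table)
        else:
            action = scheduled_ramp_step(state, config, table)
        state.cycle = cycle + 1
        state.intensity_history.append(intensity)
        state.rms_history.append(rms)
        powers.append(power_w)
        intensities.append(intensity)
        rows.append(
            {
                "cycle": cycle,
                "voltage_mvpp": voltage_before,
                "power_w": power_w,
                "isptp_wcm2": intensity,
                "rms_v": rms,
                "action": action,
            }
        )
        sustained, _ = class_amplitudes(synth, cycle * synth.pulse_period, intensity)
        update_vessel(vessel, sustained, synth.pulse_period, vessel_rng, synth)
        if vessel.ruptured:
            break

    ruptured = vessel.ruptured
    t_rupture = (
        float(vessel.rupture_instant)
        if ruptured
        else float(config.max_cycles * synth.pulse_period)
    )
    from .stats import exposure_summary

    mean_i, energy = exposure_summary(powers, intensities, duty=0.5, cycle_period=synth.pulse_period)
    return ControlledTrialResult(
        time_to_rupture=t_rupture,
        ruptured=ruptured,
        mean_sptp_intensity=mean_i,
        total_acoustic_energy=energy,
        log=pd.DataFrame(rows),
    )
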