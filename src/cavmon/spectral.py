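"""Band-resolved quantification of passive cavitation detector (PCD) signals.

During pulsed HIFU exposure, an unfocused receiving transducer records
acoustic emissions from the focal zone in 0.5-s records, one per insonation
cycle.  Bubble activity is quantified by averaging periodograms of
non-overlapping record segments and integrating the averaged spectrum over
three diagnostic bands:

* ``low_frequency`` (10-30 kHz): tissue/fluid vaporization (boiling),
* ``broadband`` (0.3-1.1 MHz): inertial cavitation,
* ``subharmonic`` (single bin at 1.65 MHz, half the 3.3-MHz drive):
  stable cavitation.

Band powers are normalized by the same band power of a pre-exposure
electronic-noise reference record, giving a decibel-scaled SNR per band and
per cycle (1-s temporal resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PCDRecord",
    "PowerSpectrum",
    "FrequencyBand",
    "BandLevels",
    "DEFAULT_BANDS",
    "averaged_power_spectrum",
    "band_energy",
    "band_snr",
    "emission_time_series",
]


@dataclass(frozen=True)
class PCDRecord:
    """One digitized PCD voltage trace for a single insonation cycle."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    cycle_index: int = 0
    trial_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided averaged periodogram.

    Normalization is ``P[k] = |X[k]|**2 / N`` for DFT ``X`` of an
    ``N``-sample rectangular-window segment, averaged over segments, with no
    one-sided doubling applied to the stored bins.  Under this convention a
    unit-amplitude sinusoid at a bin center appears with peak value ``N/4``,
    and Parseval's identity takes the form implemented by
    :meth:`total_energy`.
    """

    bin_frequencies: np.ndarray  # Hz
    power: np.ndarray
    segment_length: int
    n_segments: int
    sampling_rate: float

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def bin_width(self) -> float:
        return self.sampling_rate / self.segment_length

    def total_energy(self) -> float:
        """Mean per-segment energy ``sum_n x[n]**2`` recovered from the bins.

        Interior bins carry a factor 2 (their negative-frequency twins were
        discarded); DC and, for even ``N``, the Nyquist bin are counted once.
        """
        w = np.full(self.power.shape, 2.0)
        w[0] = 1.0
        if self.segment_length % 2 == 0:
            w[-1] = 1.0
        return float(np.sum(w * self.power))


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval selecting spectrum bins by center frequency.

    ``single_bin`` bands select only the bin whose center is nearest
    ``f_low`` (== ``f_high``), ties resolved toward the lower bin.
    """

    name: str
    f_low: float
    f_high: float
    single_bin: bool = False

    def __post_init__(self):
        if self.f_low > self.f_high:
            raise ValueError("f_low must not exceed f_high")

    def select(self, spectrum: PowerSpectrum) -> np.ndarray:
        """Boolean mask of in-band bins; DC bin always excluded."""
        f = spectrum.bin_frequencies
        if self.single_bin:
            target = 0.5 * (self.f_low + self.f_high)
            dist = np.abs(f - target)
            # ties toward the lower bin: np.argmin returns the first minimum
            idx = int(np.argmin(dist))
            mask = np.zeros(f.shape, dtype=bool)
            mask[idx] = True
        else:
            mask = (f >= self.f_low) & (f <= self.f_high)
        mask[0] = False
        return mask


DEFAULT_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("low_frequency", 10e3, 30e3),
    FrequencyBand("broadband", 0.3e6, 1.1e6),
    FrequencyBand("subharmonic", 1.65e6, 1.65e6, single_bin=True),
)


@dataclass
class BandLevels:
    """Per-cycle dB-scaled band SNR time series for one trial (1-s cadence)."""

    frame: pd.DataFrame  # columns: time_s + one per band name
    trial_id: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_s"].to_numpy()

    def snr_db(self, band_name: str) -> np.ndarray:
        return self.frame[band_name].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


def averaged_power_spectrum(record: PCDRecord, segment_length: int) -> PowerSpectrum:
    """Segment-averaged one-sided periodogram of a PCD record.

    The record is split into non-overlapping rectangular-window segments of
    ``segment_length`` samples (a trailing partial segment is discarded), the
    DFT is taken per segment, and squared magnitudes are averaged across
    segments.

    Parameters
    ----------
    record
        Input trace; must contain at least one full segment.
    segment_length
        Samples per segment; must be even and positive.  Bin width is
        ``sampling_rate / segment_length``.
    """
    if segment_length <= 0 or segment_length % 2:
        raise ValueError("segment_length must be a positive even integer")
    n = record.samples.size
    n_segments = n // segment_length
    if n_segments == 0:
        raise ValueError(
            f"record of {n} samples is shorter than one segment ({segment_length})"
        )
    x = record.samples[: n_segments * segment_length].reshape(n_segments, segment_length)
    spec = np.fft.rfft(x, axis=1)
    power = np.mean(np.abs(spec) ** 2, axis=0) / segment_length
    freqs = np.fft.rfftfreq(segment_length, d=1.0 / record.sampling_rate)
    return PowerSpectrum(
        bin_frequencies=freqs,
        power=power,
        segment_length=segment_length,
        n_segments=n_segments,
        sampling_rate=record.sampling_rate,
    )


def band_energy(spectrum: PowerSpectrum, band: FrequencyBand) -> float:
    """Sum of averaged-periodogram bins whose centers fall inside ``band``."""
    nyquist = spectrum.sampling_rate / 2.0
    if not band.single_bin and band.f_low > nyquist:
        raise ValueError(f"band {band.name} lies entirely above Nyquist ({nyquist} Hz)")
    mask = band.select(spectrum)
    if not mask.any():
        raise ValueError(f"band {band.name} selects no bins on this grid")
    return float(np.sum(spectrum.power[mask]))


def band_snr(
    signal_spectrum: PowerSpectrum,
    noise_spectrum: PowerSpectrum,
    band: FrequencyBand,
) -> float:
    """Band SNR in dB: ``10*log10(band_energy(signal)/band_energy(noise))``."""
    if signal_spectrum.segment_length != noise_spectrum.segment_length or (
        signal_spectrum.sampling_rate != noise_spectrum.sampling_rate
    ):
        raise ValueError("signal and noise spectra must share one bin grid")
    e_noise = band_energy(noise_spectrum, band)
    if e_noise <= 0:
        raise ZeroDivisionError(f"noise reference has zero energy in band {band.name}")
    e_sig = band_energy(signal_spectrum, band)
    if e_sig <= 0:
        return -np.inf
    return float(10.0 * np.log10(e_sig / e_noise))


def emission_time_series(
    records,
    noise_reference: PCDRecord,
    bands=DEFAULT_BANDS,
    segment_length: int | None = None,
) -> BandLevels:
    """Per-cycle band SNR for a sequence of PCD records.

    The noise reference is a pre-exposure record (all equipment powered, no
    drive) processed identically to the signal records.  Each record is
    timestamped at its cycle index in seconds (1-s cadence, 50% duty).

    ``segment_length`` defaults to 5,000 samples at 10 MHz, scaled to keep
    the bin width at 2 kHz for other sampling rates.
    """
    records = list(records)
    if noise_reference is None:
        raise ValueError("a noise reference record is required")
    if any(r.sampling_rate != noise_reference.sampling_rate for r in records):
        raise ValueError("all records must share the noise reference sampling rate")
    if segment_length is None:
        segment_length = int(round(noise_reference.sampling_rate / 2000.0))
        segment_length += segment_length % 2
    noise_spec = averaged_power_spectrum(noise_reference, segment_length)
    rows = []
    for rec in records:
        spec = averaged_power_spectrum(rec, segment_length)
        row = {"time_s": float(rec.cycle_index)}
        for b in bands:
            row[b.name] = band_snr(spec, noise_spec, b)
        rows.append(row)
    cols = ["time_s"] + [b.name for b in bands]
    frame = pd.DataFrame(rows, columns=cols)
    trial_id = records[0].trial_id if records else ""
    return BandLevels(frame=frame, trial_id=trial_id)
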