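"""Study-level experiment drivers composed from the pipeline stages.

These functions reproduce, against the synthetic generator, the two studies
the pipeline was built for:

* the rupture-prediction experiment — a set of constant-intensity trials at
  the measured exposure conditions, reduced to pooled per-cycle band SNR
  scores with pre-rupture/intact labels and ROC summaries;
* the rupture-suppression experiment — paired controller-active /
  controller-inactive closed-loop exposures sharing the same latent vessel,
  plus the analog-chain threshold derivation that links the two studies.

Problem sizes default to a reduced desk scale (0.01-0.05-s records at
4 MHz) so a full Monte-Carlo replication runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chain import (
    CalibrationTable,
    ChainConfig,
    ControllerConfig,
    analog_chain,
    derive_threshold,
    rms_envelope,
    run_closed_loop,
)
from .labeling import PRE_RUPTURE, detect_rupture, label_emissions
from .roc import pooled_labeled_scores, roc_curve
from .spectral import BandLevels, emission_time_series
from .synth import SyntheticConfig, constant_schedule, generate_trial

__all__ = [
    "TABLE1_INTENSITIES",
    "run_prediction_replicate",
    "prediction_aurocs",
    "derive_controller_threshold",
    "run_suppression_study",
]

# The 18 measured exposure conditions (SPTP W/cm^2) of the prediction study.
TABLE1_INTENSITIES: tuple[float, ...] = (
    15690, 15690, 20570, 20570, 20570, 20570, 20940, 21350, 21350,
    21980, 21980, 21980, 21980, 21980, 21980, 24430, 24430, 24430,
)


def run_prediction_replicate(
    seed: int,
    config: SyntheticConfig | None = None,
    intensities=TABLE1_INTENSITIES,
    max_cycles: int = 300,
):
    """One full synthetic rupture-prediction experiment.

    Generates one constant-intensity trial per entry of ``intensities``,
    computes band SNR time series, and detects rupture from the flow trace.
    Returns ``(levels_list, annotations)``.
    """
    if config is None:
        config = SyntheticConfig.desk(record_duration=0.01)
    levels_list, annotations = [], []
    for k, intensity in enumerate(intensities):
        trial = generate_trial(
            config,
            constant_schedule(intensity, max_cycles),
            seed=seed * 1000 + k,
            trial_id=f"synthetic_{k:03d}",
        )
        levels_list.append(emission_time_series(trial.records, trial.noise_reference))
        annotations.append(detect_rupture(trial.flow_trace))
    return levels_list, annotations


def prediction_aurocs(
    seed: int,
    config: SyntheticConfig | None = None,
    bands=("low_frequency", "broadband", "subharmonic"),
    window: float = 10.0,
) -> dict[str, float]:
    """Pooled AUROC per emission band for one synthetic prediction replicate."""
    levels_list, annotations = run_prediction_replicate(seed, config=config)
    return {
        band: roc_curve(*pooled_labeled_scores(levels_list, annotations, band, window)).auroc
        for band in bands
    }


def derive_controller_threshold(
    seed: int = 0,
    n_trials: int = 6,
    window: float = 10.0,
    config: SyntheticConfig | None = None,
    chain: ChainConfig | None = None,
    k: float = 1.5,
) -> tuple[float, float, float]:
    """Derive the controller RMS threshold from simulated labeled trials.

    Mirrors the original procedure: labeled PCD records are pushed through
    the software model of the analog chain, per-cycle envelope RMS values
    are pooled, the ROC corner threshold is found, and ``k`` times the
    chain's RMS noise level is subtracted.  Returns
    ``(threshold, noise_rms, corner_threshold)`` in volts RMS.
    """
    if config is None:
        config = SyntheticConfig.desk(record_duration=0.02)
    if chain is None:
        chain = ChainConfig()
    intensities = [21980, 21980, 21350, 20570, 24430, 15690][:n_trials] or [21980]
    rms_values, labels = [], []
    noise_rms_values = []
    for k_trial, intensity in enumerate(intensities):
        trial = generate_trial(
            config, constant_schedule(intensity, config.max_cycles), seed=seed * 1000 + k_trial
        )
        noise_rms_values.append(rms_envelope(analog_chain(trial.noise_reference, chain)))
        per_cycle = [rms_envelope(analog_chain(rec, chain)) for rec in trial.records]
        annotation = detect_rupture(trial.flow_trace)
        frame = pd.DataFrame(
            {"time_s": [r.cycle_index for r in trial.records], "rms": per_cycle}
        )
        labeled = label_emissions(BandLevels(frame=frame), annotation, window=window)
        keep = labeled["label"] != "excluded"
        rms_values.append(labeled.loc[keep, "rms"].to_numpy())
        labels.append((labeled.loc[keep, "label"] == PRE_RUPTURE).to_numpy())
    scores = np.concatenate(rms_values)
    y = np.concatenate(labels)
    noise_rms = float(np.mean(noise_rms_values))
    threshold = derive_threshold(scores, y, noise_rms, k=k)
    corner = threshold + k * noise_rms
    return threshold, noise_rms, corner


def run_suppression_study(
    n_pairs: int = 50,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    chain: ChainConfig | None = None,
    controller: ControllerConfig | None = None,
    table: CalibrationTable | None = None,
) -> pd.DataFrame:
    """Paired controller-active vs controller-inactive closed-loop exposures.

    Each pair shares one latent vessel draw (rupture threshold and growth
    factor); the two arms see independent signal noise.  Returns one row per
    pair with rupture times (censored at the 300-s limit), trial-mean SPTP
    intensity, and total delivered acoustic energy for both arms.
    """
    if config is None:
        config = SyntheticConfig.desk()  # 0.05-s records
    if chain is None:
        chain = ChainConfig()
    if controller is None:
        controller = ControllerConfig()
    if table is None:
        table = CalibrationTable.default()
    rows = []
    for pair in range(n_pairs):
        vessel_seed = seed * 100_000 + pair
        active = run_closed_loop(
            ControllerConfig(**{**controller.__dict__, "active": True}),
            chain, config, seed=seed * 100_000 + 2 * pair + 1,
            table=table, vessel_seed=vessel_seed,
        )
        inactive = run_closed_loop(
            ControllerConfig(**{**controller.__dict__, "active": False}),
            chain, config, seed=seed * 100_000 + 2 * pair + 2,
            table=table, vessel_seed=vessel_seed,
        )
        rows.append(
            {
                "pair": pair,
                "active_time_s": active.time_to_rupture,
                "inactive_time_s": inactive.time_to_rupture,
                "active_ruptured": active.ruptured,
                "inactive_ruptured": inactive.ruptured,
                "active_energy_j": active.total_acoustic_energy,
                "inactive_energy_j": inactive.total_acoustic_energy,
                "active_mean_intensity": active.mean_sptp_intensity,
                "inactive_mean_intensity": inactive.mean_sptp_intensity,
            }
        )
    return pd.DataFrame(rows)
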