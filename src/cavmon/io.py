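"""Fixtures, trial containers, and run configuration.

Three measured tables ship with the package as CSV fixtures:

* ``table1`` — exposure conditions and times to rupture for the 18
  rupture-prediction trials (blank time = no rupture within 300 s),
* ``table4`` — paired controller-inactive/active rupture times for the 10
  suppression pairs, with vessel type,
* ``calibration`` — the six measured drive-voltage → acoustic-power →
  focal-intensity conditions.

Synthetic trials round-trip through a directory container: PCD records in
an HDF5 file (one dataset per cycle with sampling/intensity attributes),
the flow trace as CSV, and trial metadata as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .spectral import PCDRecord
from .synth import FlowTrace, SyntheticConfig, SyntheticTrial

__all__ = [
    "load_table_fixture",
    "write_trial",
    "read_trial",
    "TrialFormatError",
    "RunConfig",
]

_FIXTURES = {"table1": "table1.csv", "table4": "table4.csv", "calibration": "calibration.csv"}


class TrialFormatError(ValueError):
    """Raised for malformed trial containers."""


def load_table_fixture(name: str) -> pd.DataFrame:
    """Load one of the shipped measured tables (``table1``/``table4``/``calibration``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    with resources.files("cavmon.data").joinpath(_FIXTURES[name]).open("r") as fh:
        frame = pd.read_csv(fh)
    if name == "table1":
        frame["censored"] = frame["time_to_rupture_s"].isna()
    return frame


def write_trial(trial: SyntheticTrial, path) -> Path:
    """Write a synthetic trial to a directory container (records.h5, flow.csv, meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "records.h5", "w") as h5:
        grp = h5.create_group("records")
        for rec, intensity in zip(trial.records, trial.exposure_schedule):
            ds = grp.create_dataset(f"cycle_{rec.cycle_index:04d}", data=rec.samples)
            ds.attrs["sampling_rate"] = rec.sampling_rate
            ds.attrs["cycle_index"] = rec.cycle_index
            ds.attrs["intensity"] = float(intensity)
        noise = h5.create_dataset("noise_reference", data=trial.noise_reference.samples)
        noise.attrs["sampling_rate"] = trial.noise_reference.sampling_rate
    flow = pd.DataFrame(
        {"time_s": trial.flow_trace.time, "current_mA": trial.flow_trace.current}
    )
    flow.to_csv(path / "flow.csv", index=False, float_format="%.17g")
    meta = {
        "seed": trial.seed,
        "trial_id": trial.trial_id,
        "true_rupture_instant": trial.true_rupture_instant,
        "config": dataclasses.asdict(trial.config),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_trial(path) -> SyntheticTrial:
    """Read a trial container written by :func:`write_trial` (lossless)."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise TrialFormatError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    config = SyntheticConfig(**meta["config"])

    records = []
    intensities = []
    with h5py.File(path / "records.h5", "r") as h5:
        if "records" not in h5 or "noise_reference" not in h5:
            raise TrialFormatError("container missing records or noise_reference")
        for name in sorted(h5["records"]):
            ds = h5["records"][name]
            if "sampling_rate" not in ds.attrs:
                raise TrialFormatError(f"dataset {name} missing sampling_rate attribute")
            records.append(
                PCDRecord(
                    samples=ds[...],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    cycle_index=int(ds.attrs["cycle_index"]),
                    trial_id=meta.get("trial_id", ""),
                )
            )
            intensities.append(float(ds.attrs["intensity"]))
        noise_ds = h5["noise_reference"]
        if "sampling_rate" not in noise_ds.attrs:
            raise TrialFormatError("noise_reference missing sampling_rate attribute")
        noise = PCDRecord(noise_ds[...], float(noise_ds.attrs["sampling_rate"]))

    flow_frame = pd.read_csv(path / "flow.csv", float_precision="round_trip")
    t = flow_frame["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise TrialFormatError("flow trace time must be strictly increasing")
    flow = FlowTrace(time=t, current=flow_frame["current_mA"].to_numpy())
    return SyntheticTrial(
        records=records,
        noise_reference=noise,
        flow_trace=flow,
        true_rupture_instant=meta["true_rupture_instant"],
        exposure_schedule=np.asarray(intensities),
        config=config,
        seed=meta["seed"],
        trial_id=meta.get("trial_id", ""),
    )


@dataclasses.dataclass
class RunConfig:
    """Round-trippable configuration for a reproducible pipeline run."""

    synthetic: dict = dataclasses.field(default_factory=dict)
    chain: dict = dataclasses.field(default_factory=dict)
    controller: dict = dataclasses.field(default_factory=dict)
    window_s: float = 10.0
    seed: int = 0
    output_dir: str = "runs"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
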