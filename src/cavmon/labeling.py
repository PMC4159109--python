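"""Rupture detection from flow metering and emission classification.

Vessel rupture is observed indirectly: saline flows through the vessel in
an open loop, and a rupture diverts flow, dropping the inline flow-meter
output.  Detectable rupture is a 3% decrease of the output current from its
pre-sonication baseline; the transit delay of the flow circuit means the
actual rupture instant precedes detection by 8 s.

Per-cycle emission levels are then split, relative to the inferred rupture
instant, into ``pre_rupture`` (within the last ``window`` seconds before
rupture, default 10 s) and ``intact_vessel`` (earlier cycles, and every
cycle of a non-rupture trial).  Cycles at or after the rupture instant are
excluded — the analysis concerns emissions from an intact vessel only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import BandLevels
from .synth import FlowTrace

__all__ = [
    "RuptureAnnotation",
    "detect_rupture",
    "label_emissions",
    "PRE_RUPTURE",
    "INTACT_VESSEL",
    "EXCLUDED",
]

PRE_RUPTURE = "pre_rupture"
INTACT_VESSEL = "intact_vessel"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class RuptureAnnotation:
    """Flow-derived rupture call for one trial.

    ``rupture_instant = detection_time - lag`` when detection occurred;
    both are ``None`` for an intact trial.
    """

    detection_time: float | None
    rupture_instant: float | None
    baseline_current: float

    @property
    def ruptured(self) -> bool:
        return self.detection_time is not None


def detect_rupture(
    trace: FlowTrace,
    drop_fraction: float = 0.03,
    lag: float = 8.0,
) -> RuptureAnnotation:
    """Find the first ``drop_fraction`` decrease of flow current from baseline.

    The baseline is the mean of samples preceding ``sonication_start``
    (falling back to the first sample if none exist).  Detection time is the
    first sample with ``current < (1 - drop_fraction) * baseline``; the
    rupture instant is ``lag`` seconds earlier.
    """
    pre = trace.current[trace.time < trace.sonication_start]
    baseline = float(np.mean(pre)) if pre.size else float(trace.current[0])
    if baseline <= 0:
        raise ValueError("flow baseline is zero; cannot detect a fractional drop")
    below = trace.current < (1.0 - drop_fraction) * baseline
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return RuptureAnnotation(None, None, baseline)
    t_detect = float(trace.time[idx[0]])
    return RuptureAnnotation(t_detect, t_detect - lag, baseline)


def label_emissions(
    levels: BandLevels,
    annotation: RuptureAnnotation,
    window: float = 10.0,
) -> pd.DataFrame:
    """Classify each emission cycle relative to the rupture instant.

    Returns a copy of the band-level frame with a ``label`` column:
    ``pre_rupture`` for ``rupture - window <= t < rupture``,
    ``intact_vessel`` for earlier cycles (or every cycle when no rupture
    occurred), ``excluded`` for cycles at or after the rupture instant.
    """
    if window < 1.0:
        raise ValueError("window must be at least 1 s")
    frame = levels.frame.copy()
    t = frame["time_s"].to_numpy()
    if not annotation.ruptured:
        frame["label"] = INTACT_VESSEL
        return frame
    r = annotation.rupture_instant
    label = np.where(
        t >= r, EXCLUDED, np.where(t >= r - window, PRE_RUPTURE, INTACT_VESSEL)
    )
    frame["label"] = label
    return frame
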