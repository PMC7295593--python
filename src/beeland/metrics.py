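"""Per-landing, per-phase summary metrics.

Each valid phase window (TL or LE) collapses the kinematic series into the
per-landing summary used by the statistical stage: phase duration, path
length, Euclidean distance and tortuosity evaluated at the phase-start
frame, and unweighted per-frame means of flight height, flight speed and
body pitch over [phase start, touchdown].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import KinematicSeries
from .segmentation import LandingAnnotation, PhaseWindows

PHASES = ("TL", "LE")

#: long-format column contract consumed by the statistical stage
METRIC_COLUMNS = ["landing_id", "condition", "day", "part_of_day", "phase", "metric", "value"]


class ExcludedLandingError(ValueError):
    """The requested phase is invalid for this landing."""

    def __init__(self, phase: str, reason: str):
        self.phase = phase
        self.reason = reason
        super().__init__(f"phase {phase} excluded: {reason}")


@dataclass(frozen=True)
class PhaseMetrics:
    """Summary metrics of one phase of one landing."""

    phase: str
    dt: float  # phase duration, s
    D: float  # path length at phase start, m
    D_E: float  # Euclidean distance at phase start, m
    T: float  # tortuosity at phase start
    H: float  # mean flight height, m
    U: float  # mean flight speed, m/s
    B: float  # mean body pitch, degrees (NaN without abdomen track)


def compute_phase_metrics(
    kin: KinematicSeries, window: PhaseWindows, phase: str
) -> PhaseMetrics:
    """Collapse one phase window into its summary metrics."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    if phase == "TL":
        if not window.tl_valid:
            raise ExcludedLandingError(phase, window.tl_reason)
        start = window.tl_start_frame
    else:
        if not window.le_valid:
            raise ExcludedLandingError(phase, window.le_reason)
        start = window.le_start_frame
    td = window.touchdown_frame
    sl = slice(start, td + 1)
    beta = float(np.nanmean(kin.beta[sl])) if kin.beta is not None else np.nan
    return PhaseMetrics(
        phase=phase,
        dt=float(-kin.t[start]),
        D=float(kin.d[start]),
        D_E=float(kin.d_E[start]),
        T=float(kin.tau[start]),
        H=float(np.mean(kin.h[sl])),
        U=float(np.mean(kin.speed[sl])),
        B=beta,
    )


def metrics_table(
    kins: list[KinematicSeries],
    windows: list[PhaseWindows],
    annotations: list[LandingAnnotation],
) -> pd.DataFrame:
    """Long-format metric table over a batch (excluded phases are skipped)."""
    rows = []
    for kin, win, ann in zip(kins, windows, annotations):
        for phase in PHASES:
            try:
                m = compute_phase_metrics(kin, win, phase)
            except ExcludedLandingError:
                continue
            for name, value in (
                ("dt", m.dt),
                ("D", m.D),
                ("D_E", m.D_E),
                ("T", m.T),
                ("H", m.H),
                ("U", m.U),
                ("B", m.B),
            ):
                rows.append(
                    {
                        "landing_id": ann.landing_id,
                        "condition": ann.condition,
                        "day": ann.day,
                        "part_of_day": ann.part_of_day,
                        "phase": phase,
                        "metric": name,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
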