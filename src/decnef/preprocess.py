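"""Percent signal change and spatiotemporal trial features.

The real-time decoder consumes, for every attention block, the ROI's
percent-signal-change values over the last five volumes of the attention
period — flattened volume-major, with no normalisation or centering so
that voxel amplitude information is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .schedule import (
    AcquisitionParams,
    Condition,
    RunSchedule,
    baseline_window_volumes,
    regulation_window_volumes,
)

N_WINDOW_VOLUMES = 5


@dataclass
class TrialFeature:
    """Flattened 5-volume x n-voxel pattern of one attention block."""

    values: np.ndarray
    label: Condition
    run_index: int
    trial_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def percent_signal_change(
    raw: np.ndarray,
    baseline_volumes: Sequence[int],
) -> np.ndarray:
    """Express each voxel as percent deviation from its baseline mean.

    psc[t, v] = 100 * (raw[t, v] - m_v) / m_v with m_v the voxel's mean
    over ``baseline_volumes``.
    """
    raw = np.asarray(raw, dtype=float)
    idx = np.asarray(list(baseline_volumes), dtype=int)
    if idx.size == 0:
        raise ValueError("baseline window is empty")
    m = raw[idx].mean(axis=0)
    zero = np.flatnonzero(m == 0)
    if zero.size:
        raise ValueError(f"baseline mean is zero for voxel(s) {zero.tolist()}")
    return 100.0 * (raw - m) / m


def psc_from_run(raw: np.ndarray, schedule: RunSchedule, params: AcquisitionParams) -> np.ndarray:
    """PSC using the run kind's baseline window (fixation or first rest)."""
    return percent_signal_change(raw, baseline_window_volumes(schedule, params))


def extract_trial_features(
    psc: np.ndarray,
    schedule: RunSchedule,
    params: Optional[AcquisitionParams] = None,
    shift: int = 2,
) -> List[TrialFeature]:
    """One feature per block: the 5-volume window, flattened volume-major.

    Row ``t`` of the window precedes row ``t+1`` in the flattened vector
    (volume-major order); values are copied bit-identically from the PSC
    matrix with no scaling or centering.
    """
    if params is None:
        params = AcquisitionParams()
    psc = np.asarray(psc, dtype=float)
    features = []
    for block in schedule.blocks:
        window = regulation_window_volumes(block, params, shift, n_volumes=psc.shape[0])
        features.append(
            TrialFeature(
                values=psc[window].ravel(order="C"),
                label=block.condition,
                run_index=schedule.run_index,
                trial_index=block.block_index,
            )
        )
    return features


def feature_matrix(features: Sequence[TrialFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Stack features into (X, y) with y = +1 interoceptive / -1 exteroceptive."""
    X = np.vstack([f.values for f in features])
    y = np.array([1 if f.label is Condition.INTEROCEPTIVE else -1 for f in features])
    return X, y
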