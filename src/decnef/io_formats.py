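"""Interchange formats: BIDS-style events TSV, NIfTI export, feedback and
heartbeat tables, and the deterministic fixture bundle used in tests.

TSV dialect: tab-separated UTF-8, "." decimal separator, "n/a" for missing
values (the BIDS convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .feedback import FeedbackRecord
from .schedule import (
    AcquisitionParams,
    BlockEvent,
    Condition,
    RunKind,
    RunSchedule,
)
from .synth import HeartbeatTrial, RoiTimeSeries

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "block_index"]


def write_events(path, schedule: RunSchedule) -> None:
    """Serialise a run schedule as a BIDS-style events TSV.

    One row per block; ``onset``/``duration`` cover the whole block and
    ``trial_type`` is "heart" or "target".  Phase durations and the run
    kind are stored in comment-free extra columns so the file round-trips.
    """
    rows = []
    for b in schedule.blocks:
        rows.append(
            {
                "onset": b.onset_seconds,
                "duration": b.duration_seconds,
                "trial_type": b.condition.trial_type,
                "block_index": b.block_index,
                "rest_seconds": b.rest_seconds,
                "regulation_seconds": b.regulation_seconds,
                "rating_seconds": b.rating_seconds,
                "feedback_seconds": b.feedback_seconds,
                "run_kind": schedule.kind.value,
                "run_index": schedule.run_index,
                "n_volumes": schedule.n_volumes,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> RunSchedule:
    """Parse an events TSV written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing column(s): {missing}")
    blocks = []
    for _, row in df.sort_values("onset").iterrows():
        blocks.append(
            BlockEvent(
                condition=Condition.from_trial_type(str(row["trial_type"])),
                block_index=int(row["block_index"]),
                rest_seconds=float(row.get("rest_seconds", 0.0)),
                regulation_seconds=float(row.get("regulation_seconds", 10.0)),
                rating_seconds=float(row.get("rating_seconds", 0.0)),
                feedback_seconds=float(row.get("feedback_seconds", 0.0)),
                onset_seconds=float(row["onset"]),
            )
        )
    kind = RunKind(str(df["run_kind"].iloc[0])) if "run_kind" in df else RunKind.REGULATION
    run_index = int(df["run_index"].iloc[0]) if "run_index" in df else 1
    n_volumes = (
        int(df["n_volumes"].iloc[0])
        if "n_volumes" in df
        else int(math.ceil((blocks[-1].onset_seconds + blocks[-1].duration_seconds) / 2.0))
    )
    return RunSchedule(kind=kind, run_index=run_index, blocks=blocks, n_volumes=n_volumes)


def _roi_grid_shape(n_voxels: int) -> tuple[int, int, int]:
    """Near-cubic 3-D grid large enough to hold ``n_voxels`` voxels."""
    side = int(math.ceil(n_voxels ** (1.0 / 3.0)))
    nx = side
    ny = side
    nz = int(math.ceil(n_voxels / (nx * ny)))
    return nx, ny, nz


def export_nifti(path, ts: RoiTimeSeries) -> np.ndarray:
    """Write a run as 4-D NIfTI on a synthetic 3-D grid; returns the mask.

    Voxels are laid out in C order on a near-cubic grid; unoccupied grid
    cells are zero and excluded from the boolean ROI mask.  The TR is
    stored in the header (pixdim[4] / zooms).
    """
    import nibabel as nib

    n_vol, n_vox = ts.data.shape
    nx, ny, nz = _roi_grid_shape(n_vox)
    vol = np.zeros((nx * ny * nz, n_vol))
    vol[:n_vox] = ts.data.T
    img_data = vol.reshape(nx, ny, nz, n_vol)
    mask = np.zeros(nx * ny * nz, dtype=bool)
    mask[:n_vox] = True
    mask = mask.reshape(nx, ny, nz)

    img = nib.Nifti1Image(img_data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ts.params.tr_seconds))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return mask


def import_nifti(path, mask: np.ndarray, schedule: RunSchedule, params: AcquisitionParams) -> RoiTimeSeries:
    """Read a 4-D NIfTI back into a volumes x voxels ROI matrix."""
    import nibabel as nib

    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    if abs(tr - params.tr_seconds) > 1e-6:
        raise ValueError(f"header TR {tr} does not match acquisition TR {params.tr_seconds}")
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    roi = data[mask].T  # volumes x voxels, C-order voxel traversal
    return RoiTimeSeries(data=roi, params=params, schedule=schedule)


def write_feedback_records(path, records: Sequence[FeedbackRecord]) -> None:
    rows = [
        {
            "run_index": r.run_index,
            "trial_index": r.trial_index,
            "condition": r.condition.value,
            "decision": r.decision,
            "probability": r.probability,
            "score": r.score,
            "correct": int(r.correct),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_feedback_records(path) -> List[FeedbackRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return [
        FeedbackRecord(
            run_index=int(r.run_index),
            trial_index=int(r.trial_index),
            condition=Condition(r.condition),
            decision=float(r.decision),
            probability=float(r.probability),
            score=float(r.score),
            correct=bool(r.correct),
        )
        for r in df.itertuples()
    ]


def write_heartbeat_trials(path, rows: Dict[str, Dict[str, Sequence[HeartbeatTrial]]]) -> None:
    """``rows`` maps subject -> session ("pre"/"post") -> trials."""
    out = []
    for subject, sessions in rows.items():
        for session, trials in sessions.items():
            for t in trials:
                out.append(
                    {
                        "subject": subject,
                        "session": session,
                        "duration": t.duration_seconds,
                        "recorded": t.recorded_beats,
                        "reported": t.reported_beats,
                        "confidence": t.confidence,
                    }
                )
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_heartbeat_trials(path) -> Dict[str, Dict[str, List[HeartbeatTrial]]]:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    out: Dict[str, Dict[str, List[HeartbeatTrial]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.subject), {}).setdefault(str(r.session), []).append(
            HeartbeatTrial(
                duration_seconds=int(r.duration),
                recorded_beats=int(r.recorded),
                reported_beats=int(r.reported),
                confidence=float(r.confidence),
            )
        )
    return out


@dataclass
class FixtureBundle:
    """Small deterministic dataset reused across the test suite."""

    subjects: list
    params: AcquisitionParams
    heartbeat_perfect: List[HeartbeatTrial] = field(default_factory=list)
    svm_X: np.ndarray = None
    svm_y: np.ndarray = None


def make_fixtures(seed: int = 1234) -> FixtureBundle:
    """Tiny cohort (2 contingent + 2 sham subjects, 20 voxels) plus
    hand-checkable heartbeat and SVM toy instances, byte-stable per seed."""
    from .synth import PopulationConfig, simulate_cohort

    params = AcquisitionParams(n_voxels=20)
    pop = PopulationConfig(pattern_sd=1.0, noise_sd=0.8)
    subjects = simulate_cohort(2, 2, pop, seed=seed, params=params)

    heartbeat_perfect = [
        HeartbeatTrial(duration_seconds=d, recorded_beats=d, reported_beats=d, confidence=80.0)
        for d in (15, 25, 35, 45, 55, 65)
    ]
    rng = np.random.default_rng(seed)
    n = 10
    svm_X = rng.normal(size=(n, 3))
    svm_y = np.where(rng.random(n) < 0.5, 1, -1)
    svm_y[0], svm_y[1] = 1, -1  # force both classes
    svm_X += 0.5 * svm_y[:, None]
    return FixtureBundle(
        subjects=subjects,
        params=params,
        heartbeat_perfect=heartbeat_perfect,
        svm_X=svm_X,
        svm_y=svm_y,
    )
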