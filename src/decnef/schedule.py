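"""Block/trial timing for the decoder-training task and the regulation runs.

The session comprises one decoder-training run followed by three
neurofeedback regulation runs.  Both run kinds present 24 attention blocks
(12 interoceptive "heart" blocks alternating with 12 exteroceptive "target"
blocks).  A decoder-training trial is a 12-s rest followed by a 10-s
attention period; a regulation block is rest 10 s, regulation 10 s,
rating 6 s, feedback 4 s, and each regulation run opens with a 20-s
fixation baseline.

All volume indices are 0-based and refer to the time series *after* dummy
volumes have been discarded; intervals in seconds are half-open.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import List, Optional


class Condition(str, enum.Enum):
    """Instructed attentional state of a block."""

    INTEROCEPTIVE = "interoceptive"
    EXTEROCEPTIVE = "exteroceptive"

    @property
    def trial_type(self) -> str:
        """BIDS events trial_type label ("heart" / "target")."""
        return "heart" if self is Condition.INTEROCEPTIVE else "target"

    @classmethod
    def from_trial_type(cls, trial_type: str) -> "Condition":
        try:
            return {"heart": cls.INTEROCEPTIVE, "target": cls.EXTEROCEPTIVE}[trial_type]
        except KeyError:
            raise ValueError(f"unknown trial_type {trial_type!r}; expected 'heart' or 'target'")


class RunKind(str, enum.Enum):
    DECODER_TRAINING = "decoder_training"
    REGULATION = "regulation"


N_BLOCKS = 24
N_PER_CONDITION = 12


@dataclass(frozen=True)
class AcquisitionParams:
    """EPI acquisition constants used throughout the pipeline.

    Parameters
    ----------
    tr_seconds : float
        Repetition time (sampling interval) of the functional series.
    n_dummy_volumes : int
        Leading volumes discarded for T1 equilibration; all volume indices
        in this package are post-discard.
    baseline_seconds : float
        Duration of the opening fixation period of a regulation run, used
        as the percent-signal-change baseline.  Must be a multiple of TR.
    n_voxels : int
        Number of voxels in the region-of-interest mask.
    """

    tr_seconds: float = 2.0
    n_dummy_volumes: int = 3
    baseline_seconds: float = 20.0
    n_voxels: int = 150

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_dummy_volumes < 0:
            raise ValueError("n_dummy_volumes must be >= 0")
        ratio = self.baseline_seconds / self.tr_seconds
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("baseline_seconds must be an integer multiple of tr_seconds")
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")

    @property
    def baseline_volumes(self) -> int:
        return int(round(self.baseline_seconds / self.tr_seconds))


@dataclass(frozen=True)
class BlockEvent:
    """One attention block with its internal phase durations.

    ``onset_seconds`` marks the start of the block (the rest phase) from
    run start.  The attention (regulation) period spans
    ``[onset + rest, onset + rest + regulation)`` seconds.
    """

    condition: Condition
    block_index: int
    rest_seconds: float
    regulation_seconds: float
    rating_seconds: float
    feedback_seconds: float
    onset_seconds: float

    def __post_init__(self) -> None:
        for name in ("rest_seconds", "regulation_seconds", "rating_seconds", "feedback_seconds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def duration_seconds(self) -> float:
        return (
            self.rest_seconds + self.regulation_seconds + self.rating_seconds + self.feedback_seconds
        )

    @property
    def regulation_onset_seconds(self) -> float:
        return self.onset_seconds + self.rest_seconds

    @property
    def regulation_offset_seconds(self) -> float:
        return self.regulation_onset_seconds + self.regulation_seconds


@dataclass(frozen=True)
class RunSchedule:
    """Ordered block timing of one run plus its (post-dummy) volume count."""

    kind: RunKind
    run_index: int
    blocks: List[BlockEvent] = field(default_factory=list)
    n_volumes: int = 0

    def __post_init__(self) -> None:
        if len(self.blocks) != N_BLOCKS:
            raise ValueError(f"expected {N_BLOCKS} blocks, got {len(self.blocks)}")
        n_intero = sum(b.condition is Condition.INTEROCEPTIVE for b in self.blocks)
        if n_intero != N_PER_CONDITION:
            raise ValueError("expected 12 blocks per condition")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.condition is b.condition:
                raise ValueError("conditions must strictly alternate")
            if b.onset_seconds <= a.onset_seconds:
                raise ValueError("block onsets must be strictly increasing")

    @property
    def duration_seconds(self) -> float:
        last = self.blocks[-1]
        return last.onset_seconds + last.duration_seconds

    def conditions(self) -> List[Condition]:
        return [b.condition for b in self.blocks]


def build_schedule(
    kind: RunKind | str,
    params: Optional[AcquisitionParams] = None,
    run_index: int = 0,
    *,
    first_condition: Condition = Condition.INTEROCEPTIVE,
    n_volumes_override: Optional[int] = None,
) -> RunSchedule:
    """Construct the canonical timing of one run.

    Decoder-training runs consist of 24 cycles of 12-s rest + 10-s attention
    (22 s per trial).  Regulation runs open with the fixation baseline and
    then present 24 cycles of rest 10 s / regulation 10 s / rating 6 s /
    feedback 4 s (30 s per block).  The run's volume count is derived from
    the schedule; ``n_volumes_override`` truncates or pads (with rest) to a
    stated scanner volume count instead.
    """
    if params is None:
        params = AcquisitionParams()
    kind = RunKind(kind)
    if kind is RunKind.DECODER_TRAINING:
        if run_index != 0:
            raise ValueError("decoder-training run must have run_index 0")
        rest, regulation, rating, fb = 12.0, 10.0, 0.0, 0.0
        start = 0.0
    else:
        if run_index not in (1, 2, 3):
            raise ValueError("regulation runs have run_index in {1, 2, 3}")
        rest, regulation, rating, fb = 10.0, 10.0, 6.0, 4.0
        start = params.baseline_seconds
    cycle = rest + regulation + rating + fb

    blocks = []
    cond = first_condition
    for k in range(N_BLOCKS):
        blocks.append(
            BlockEvent(
                condition=cond,
                block_index=k,
                rest_seconds=rest,
                regulation_seconds=regulation,
                rating_seconds=rating,
                feedback_seconds=fb,
                onset_seconds=start + k * cycle,
            )
        )
        cond = (
            Condition.EXTEROCEPTIVE if cond is Condition.INTEROCEPTIVE else Condition.INTEROCEPTIVE
        )

    # decoder-training runs close with one final rest period, so the last
    # trial's (shifted) feature window stays inside the acquisition
    trailing_rest = rest if kind is RunKind.DECODER_TRAINING else 0.0
    total_seconds = start + N_BLOCKS * cycle + trailing_rest
    n_volumes = int(math.ceil(total_seconds / params.tr_seconds - 1e-9))
    if n_volumes_override is not None:
        n_volumes = int(n_volumes_override)
    return RunSchedule(kind=kind, run_index=run_index, blocks=blocks, n_volumes=n_volumes)


def regulation_window_volumes(
    block: BlockEvent,
    params: AcquisitionParams,
    hemodynamic_shift_volumes: int = 2,
    n_volumes: Optional[int] = None,
) -> List[int]:
    """Volume indices of the last five attention-period volumes of a block.

    The window ends at the regulation offset (in volumes) translated forward
    by ``hemodynamic_shift_volumes`` to compensate for the haemodynamic
    delay; indices are post-dummy and 0-based.
    """
    n_window = 5
    span = block.regulation_seconds / params.tr_seconds
    if span + 1e-9 < n_window:
        raise ValueError("regulation period spans fewer than 5 volumes at this TR")
    end = int(round(block.regulation_offset_seconds / params.tr_seconds)) + hemodynamic_shift_volumes
    start = end - n_window
    if start < 0:
        raise ValueError("feature window starts before run onset")
    if n_volumes is not None and end > n_volumes:
        raise ValueError(
            f"feature window [{start}, {end}) exceeds run length of {n_volumes} volumes"
        )
    return list(range(start, end))


def baseline_window_volumes(schedule: RunSchedule, params: AcquisitionParams) -> List[int]:
    """Volumes forming the percent-signal-change baseline of a run.

    Regulation runs use the opening fixation period; the decoder-training
    run has no fixation, so its first rest period stands in.
    """
    if schedule.kind is RunKind.REGULATION:
        n = params.baseline_volumes
    else:
        n = int(round(schedule.blocks[0].rest_seconds / params.tr_seconds))
    if n < 1:
        raise ValueError("baseline window is empty")
    return list(range(n))
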