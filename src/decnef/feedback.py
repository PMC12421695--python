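"""Neurofeedback scores, trial correctness, run summaries, learning effect.

The displayed NF score is 100 x P(y=1|x) on interoceptive blocks and
100 x (1 - P(y=1|x)) on exteroceptive blocks, so that higher always means
"more like the instructed state".  A trial counts as correctly classified
only when its score strictly exceeds 50; classification accuracy (CA) is
the fraction of a run's 24 trials that are correct.  The learning effect
of any run-wise series is Run 3 minus the mean of Runs 1 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .decoder import DecoderModel
from .preprocess import TrialFeature
from .schedule import Condition

CORRECT_THRESHOLD = 50.0


@dataclass
class FeedbackRecord:
    """Outcome of one feedback computation for a single trial."""

    run_index: int
    trial_index: int
    condition: Condition
    decision: float
    probability: float
    score: float
    correct: bool


@dataclass
class RunSummary:
    """Displayed-score summary of one regulation run (24 trials)."""

    run_index: int
    mean_score: float
    classification_accuracy: float
    mean_score_intero: float
    mean_score_extero: float

    def to_dict(self) -> Dict:
        return {
            "run_index": self.run_index,
            "mean_score": self.mean_score,
            "classification_accuracy": self.classification_accuracy,
            "mean_score_intero": self.mean_score_intero,
            "mean_score_extero": self.mean_score_extero,
        }


def nf_score(probability: float, condition: Condition) -> float:
    """Map a calibrated interoceptive probability to the displayed score."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability {probability} outside [0, 1]")
    if condition is Condition.INTEROCEPTIVE:
        return 100.0 * probability
    return 100.0 * (1.0 - probability)


def trial_feedback(
    model: DecoderModel, feature: TrialFeature, condition: Condition | None = None
) -> FeedbackRecord:
    """Full per-trial feedback: decision -> probability -> score -> correct."""
    if condition is None:
        condition = feature.label
    f = model.decision_value(feature)
    p = model.probability(feature)
    score = nf_score(p, condition)
    return FeedbackRecord(
        run_index=feature.run_index,
        trial_index=feature.trial_index,
        condition=condition,
        decision=f,
        probability=p,
        score=score,
        correct=score > CORRECT_THRESHOLD,
    )


def summarise_run(records: Sequence[FeedbackRecord]) -> RunSummary:
    """Mean displayed score and CA over the run's feedback records."""
    if not records:
        raise ValueError("no records to summarise")
    scores = np.array([r.score for r in records])
    intero = [r.score for r in records if r.condition is Condition.INTEROCEPTIVE]
    extero = [r.score for r in records if r.condition is Condition.EXTEROCEPTIVE]
    return RunSummary(
        run_index=records[0].run_index,
        mean_score=float(scores.mean()),
        classification_accuracy=float(np.mean([r.correct for r in records])),
        mean_score_intero=float(np.mean(intero)) if intero else float("nan"),
        mean_score_extero=float(np.mean(extero)) if extero else float("nan"),
    )


def summarise_scores(run_index: int, scores: Sequence[float], conditions: Sequence[Condition]) -> RunSummary:
    """RunSummary from bare displayed scores (used for sham sequences)."""
    scores = np.asarray(scores, dtype=float)
    intero = scores[[c is Condition.INTEROCEPTIVE for c in conditions]]
    extero = scores[[c is Condition.EXTEROCEPTIVE for c in conditions]]
    return RunSummary(
        run_index=run_index,
        mean_score=float(scores.mean()),
        classification_accuracy=float(np.mean(scores > CORRECT_THRESHOLD)),
        mean_score_intero=float(intero.mean()) if intero.size else float("nan"),
        mean_score_extero=float(extero.mean()) if extero.size else float("nan"),
    )


def learning_effect(run1: float, run2: float, run3: float) -> float:
    """Run 3 minus the mean of Runs 1 and 2 (works for scores and CA)."""
    for v in (run1, run2, run3):
        if not np.isfinite(v):
            raise ValueError("run means must be finite")
    return run3 - 0.5 * (run1 + run2)


def learning_effects_from_summaries(summaries: List[RunSummary]) -> Dict[str, float]:
    """Score- and CA-based learning effects from three run summaries."""
    by_run = {s.run_index: s for s in summaries}
    if set(by_run) != {1, 2, 3}:
        raise ValueError("need summaries for runs 1, 2 and 3")
    return {
        "le_score": learning_effect(
            by_run[1].mean_score, by_run[2].mean_score, by_run[3].mean_score
        ),
        "le_ca": learning_effect(
            by_run[1].classification_accuracy,
            by_run[2].classification_accuracy,
            by_run[3].classification_accuracy,
        ),
    }
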