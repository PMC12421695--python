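"""Heartbeat-counting scores and the subject-level brain-behaviour statistics.

Interoceptive accuracy of a session is the mean over its six trials of
1 - |recorded - reported| / recorded; the score is not clamped and may go
negative for gross over-reporting.  Group statistics cover the one-sample
t-test on the learning effect, the Pearson correlation between learning
effect and accuracy change with its Fisher confidence interval, and the
between-group Fisher r-to-z comparison.  The formulas are implemented
directly so that every reported quantity is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .synth import HeartbeatTrial


@dataclass
class SubjectOutcome:
    """Per-subject regulation and behavioural outcome summary."""

    subject_id: str
    group: str
    ia_pre: float
    ia_post: float
    confidence_pre: float
    confidence_post: float
    le_score: float
    le_ca: float
    bpm_actual_pre: float
    bpm_actual_post: float
    bpm_perceived_pre: float
    bpm_perceived_post: float

    @property
    def delta_ia(self) -> float:
        return self.ia_post - self.ia_pre

    def to_dict(self) -> Dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["delta_ia"] = self.delta_ia
        return d


def interoceptive_accuracy(trials: Sequence[HeartbeatTrial]) -> float:
    """Mean of 1 - |recorded - reported| / recorded over the session."""
    if not trials:
        raise ValueError("no trials")
    acc = 0.0
    for t in trials:
        if t.recorded_beats <= 0:
            raise ValueError("recorded_beats must be positive")
        acc += 1.0 - abs(t.recorded_beats - t.reported_beats) / t.recorded_beats
    return acc / len(trials)


def bpm_summary(trials: Sequence[HeartbeatTrial]) -> tuple[float, float]:
    """(actual, perceived) beats-per-minute averaged across trials."""
    if not trials:
        raise ValueError("no trials")
    actual = np.mean([60.0 * t.recorded_beats / t.duration_seconds for t in trials])
    perceived = np.mean([60.0 * t.reported_beats / t.duration_seconds for t in trials])
    return float(actual), float(perceived)


def mean_confidence(trials: Sequence[HeartbeatTrial]) -> float:
    return float(np.mean([t.confidence for t in trials]))


# -- statistics (direct formulas) ------------------------------------------


def one_sample_t(values: Sequence[float]) -> Dict[str, float]:
    """One-sample t-test against zero with Cohen's d and 95% CI of the mean."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        t_stat = 0.0 if mean == 0 else math.inf * np.sign(mean)
        d = 0.0 if mean == 0 else math.inf * np.sign(mean)
    else:
        t_stat = mean / (sd / math.sqrt(n))
        d = mean / sd
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df) if np.isfinite(t_stat) else 0.0
    tcrit = stats.t.ppf(0.975, df)
    half = tcrit * sd / math.sqrt(n)
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "t": float(t_stat),
        "df": df,
        "p": float(p),
        "cohens_d": float(d),
        "ci_low": mean - half,
        "ci_high": mean + half,
    }


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Pearson r, its t-test p-value and the Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need n >= 3 paired observations")
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("degenerate variance")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t_stat), n - 2)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo, hi = float("nan"), float("nan")
    return {"n": n, "r": r, "p": float(p), "ci_low": lo, "ci_high": hi}


def fisher_r_to_z_test(
    r1: float, n1: int, r2: float, n2: int, alternative: str = "greater"
) -> Dict[str, float]:
    """Compare two independent correlations via the Fisher transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); one-tailed
    (r1 > r2) by default.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 per group")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError("alternative must be greater/less/two-sided")
    return {"z": float(z), "p": float(p)}


def group_statistics(outcomes_by_group: Dict[str, List[SubjectOutcome]]) -> Dict:
    """Per-group learning-effect tests and brain-behaviour correlations.

    For each group: one-sample t on the score- and CA-based learning
    effects; Pearson correlations of each learning effect with the change
    in interoceptive accuracy; descriptives of accuracy, confidence and
    heart rates.  When both an "NF" and a "Sham" group are present, the
    CA- and score-based correlations are compared between groups with a
    one-tailed Fisher r-to-z test.
    """
    report: Dict = {"groups": {}}
    for name, outs in outcomes_by_group.items():
        le_score = [o.le_score for o in outs]
        le_ca = [o.le_ca for o in outs]
        delta = [o.delta_ia for o in outs]
        g: Dict = {
            "n": len(outs),
            "t_le_score": one_sample_t(le_score),
            "t_le_ca": one_sample_t(le_ca),
            "descriptives": {
                "ia_pre_mean": float(np.mean([o.ia_pre for o in outs])),
                "ia_post_mean": float(np.mean([o.ia_post for o in outs])),
                "delta_ia_mean": float(np.mean(delta)),
                "confidence_pre_mean": float(np.mean([o.confidence_pre for o in outs])),
                "confidence_post_mean": float(np.mean([o.confidence_post for o in outs])),
                "bpm_actual_pre_mean": float(np.mean([o.bpm_actual_pre for o in outs])),
                "bpm_actual_post_mean": float(np.mean([o.bpm_actual_post for o in outs])),
                "bpm_perceived_pre_mean": float(np.mean([o.bpm_perceived_pre for o in outs])),
                "bpm_perceived_post_mean": float(np.mean([o.bpm_perceived_post for o in outs])),
            },
        }
        if len(outs) >= 3:
            g["r_le_score_delta_ia"] = pearson_with_ci(le_score, delta)
            g["r_le_ca_delta_ia"] = pearson_with_ci(le_ca, delta)
        report["groups"][name] = g
    if {"NF", "Sham"} <= set(report["groups"]):
        nf, sh = report["groups"]["NF"], report["groups"]["Sham"]
        if "r_le_ca_delta_ia" in nf and "r_le_ca_delta_ia" in sh:
            report["fisher_ca"] = fisher_r_to_z_test(
                nf["r_le_ca_delta_ia"]["r"], nf["n"], sh["r_le_ca_delta_ia"]["r"], sh["n"]
            )
            report["fisher_score"] = fisher_r_to_z_test(
                nf["r_le_score_delta_ia"]["r"], nf["n"], sh["r_le_score_delta_ia"]["r"], sh["n"]
            )
    return report
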