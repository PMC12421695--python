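"""Statistically matched, non-contingent ("yoked") sham feedback scores.

The sham generator is fitted on the pooled displayed scores of the
contingent-feedback group.  Scores are binned into fixed-width categories
on [0, 100]; the generator stores the unconditional category distribution,
a first-order category transition table estimated from consecutive
within-run score pairs, and the empirical score pool of each category.

Sampling one trial proceeds in two stages: the trial's success (score
strictly above 50) is first drawn from the run-specific correct
classification rate of the source group; the score is then sampled from
the previous trial's transition row — or the unconditional distribution
for the first trial or an unobserved row — truncated and renormalised to
the success/failure range, with actual values drawn from the stored
empirical pools.  The resulting sequences mimic the marginal distribution
and temporal structure of real feedback while carrying no information
about the recipient's brain activity.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .feedback import CORRECT_THRESHOLD

#: run-specific correct-classification rates (%) of the source group, runs 1-3
DEFAULT_RUN_SUCCESS_RATES = (48.512, 58.589, 62.500)
N_TRIALS_PER_RUN = 24


class ShamScoreGenerator(BaseEstimator):
    """Empirical sham-score model with fit/sample semantics.

    Parameters
    ----------
    bin_width : float
        Width of the score categories on [0, 100].
    estimate_rates : bool
        When True, the per-run success rates are re-estimated from the
        fitted scores as the fraction strictly above 50; otherwise the
        published defaults are used.
    transition_on : {"bins", "success"}
        Conditioning of the transition table: score categories (default)
        or the binary success/failure category of the previous trial.
    """

    def __init__(
        self,
        bin_width: float = 10.0,
        estimate_rates: bool = False,
        transition_on: str = "bins",
    ):
        self.bin_width = bin_width
        self.estimate_rates = estimate_rates
        self.transition_on = transition_on

    # -- fitting -----------------------------------------------------------

    def fit(self, scores_by_run: Sequence[Sequence[float]]) -> "ShamScoreGenerator":
        """Estimate distributions from per-run lists of displayed scores.

        ``scores_by_run`` holds one flat list per regulation run (1..3);
        each list concatenates subjects, in within-subject trial order.
        Transitions are counted over consecutive within-run, within-subject
        pairs (subject boundaries every 24 trials).
        """
        if self.transition_on not in ("bins", "success"):
            raise ValueError("transition_on must be 'bins' or 'success'")
        if self.bin_width <= 0 or 100.0 % self.bin_width:
            raise ValueError("bin_width must divide 100")
        runs = [np.asarray(list(r), dtype=float) for r in scores_by_run]
        if not runs or any(r.size == 0 for r in runs):
            raise ValueError("each run needs at least one score")
        allscores = np.concatenate(runs)
        if allscores.min() < 0 or allscores.max() > 100:
            raise ValueError("scores must lie in [0, 100]")

        self.n_bins_ = int(round(100.0 / self.bin_width))
        self.edges_ = np.linspace(0.0, 100.0, self.n_bins_ + 1)

        bins = self._bin_of(allscores)
        counts = np.bincount(bins, minlength=self.n_bins_).astype(float)
        self.unconditional_ = counts / counts.sum()
        self.pools_ = [allscores[bins == k] for k in range(self.n_bins_)]

        n_states = 2 if self.transition_on == "success" else self.n_bins_
        trans = np.zeros((n_states, self.n_bins_))
        for r in runs:
            for start in range(0, r.size, N_TRIALS_PER_RUN):
                seq = r[start : start + N_TRIALS_PER_RUN]
                prev_state = self._state_of(seq[:-1])
                nxt = self._bin_of(seq[1:])
                np.add.at(trans, (prev_state, nxt), 1.0)
        row_sums = trans.sum(axis=1)
        self.transition_ = np.divide(
            trans, row_sums[:, None], out=np.zeros_like(trans), where=row_sums[:, None] > 0
        )
        self.transition_observed_ = row_sums > 0

        if self.estimate_rates:
            self.run_success_rates_ = [
                100.0 * float(np.mean(r > CORRECT_THRESHOLD)) for r in runs
            ]
        else:
            self.run_success_rates_ = list(DEFAULT_RUN_SUCCESS_RATES[: len(runs)])
        self._build_restricted()
        return self

    def _bin_of(self, scores: np.ndarray) -> np.ndarray:
        b = np.minimum((np.asarray(scores) / self.bin_width).astype(int), self.n_bins_ - 1)
        return b

    def _state_of(self, scores: np.ndarray) -> np.ndarray:
        if self.transition_on == "success":
            return (np.asarray(scores) > CORRECT_THRESHOLD).astype(int)
        return self._bin_of(scores)

    def _build_restricted(self) -> None:
        """Precompute range-restricted samplers for fast trial generation.

        For each success/failure outcome: the fraction of every bin's pool
        inside the range, the restricted pools, and the restricted +
        renormalised unconditional and transition distributions.
        """
        succ_masks = [p > CORRECT_THRESHOLD for p in self.pools_]
        self._pools_r_ = {
            True: [p[m] for p, m in zip(self.pools_, succ_masks)],
            False: [p[~m] for p, m in zip(self.pools_, succ_masks)],
        }
        frac_succ = np.array(
            [m.mean() if m.size else 0.0 for m in succ_masks]
        )
        self._bin_frac_ = {True: frac_succ, False: 1.0 - frac_succ}
        self._uncond_r_, self._trans_r_, self._trans_r_ok_ = {}, {}, {}
        for success in (True, False):
            u = self.unconditional_ * self._bin_frac_[success]
            total = u.sum()
            # a range with no fitted mass only errors if sampling needs it
            self._uncond_r_[success] = u / total if total > 0 else u
            tr = self.transition_ * self._bin_frac_[success][None, :]
            sums = tr.sum(axis=1)
            ok = self.transition_observed_ & (sums > 0)
            self._trans_r_[success] = np.divide(
                tr, sums[:, None], out=np.zeros_like(tr), where=sums[:, None] > 0
            )
            self._trans_r_ok_[success] = ok

    # -- sampling ----------------------------------------------------------

    def sample_trial(
        self,
        run_index: int,
        prev_score: Optional[float],
        rng: np.random.Generator,
    ) -> float:
        """Draw one sham score for regulation run ``run_index`` (1-based)."""
        rate = self.run_success_rates_[run_index - 1] / 100.0
        success = bool(rng.random() < rate)
        if self._uncond_r_[success].sum() <= 0:
            raise ValueError(
                f"no fitted scores in the required {'success' if success else 'failure'} range"
            )
        if prev_score is None:
            probs = self._uncond_r_[success]
        else:
            state = int(self._state_of(np.array([prev_score]))[0])
            if self._trans_r_ok_[success][state]:
                probs = self._trans_r_[success][state]
            else:
                probs = self._uncond_r_[success]
        k = int(rng.choice(self.n_bins_, p=probs))
        pool = self._pools_r_[success][k]
        if pool.size == 0:
            raise RuntimeError("internal: sampled a bin with an empty restricted pool")
        return float(pool[rng.integers(pool.size)])

    def sample_session(self, rng: np.random.Generator, n_runs: int = 3) -> np.ndarray:
        """Full sham session: ``n_runs`` x 24 chained scores.

        The first trial of the session samples unconditionally; every later
        trial chains on its predecessor, across run boundaries.
        """
        out = np.empty((n_runs, N_TRIALS_PER_RUN))
        prev: Optional[float] = None
        for r in range(n_runs):
            for t in range(N_TRIALS_PER_RUN):
                prev = self.sample_trial(r + 1, prev, rng)
                out[r, t] = prev
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> Dict:
        return {
            "bin_width": self.bin_width,
            "transition_on": self.transition_on,
            "edges": self.edges_.tolist(),
            "unconditional": self.unconditional_.tolist(),
            "transition": self.transition_.tolist(),
            "transition_observed": self.transition_observed_.tolist(),
            "pools": [p.tolist() for p in self.pools_],
            "run_success_rates": list(self.run_success_rates_),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: Dict) -> "ShamScoreGenerator":
        gen = cls(bin_width=float(d["bin_width"]), transition_on=d["transition_on"])
        gen.n_bins_ = len(d["unconditional"])
        gen.edges_ = np.asarray(d["edges"], dtype=float)
        gen.unconditional_ = np.asarray(d["unconditional"], dtype=float)
        gen.transition_ = np.asarray(d["transition"], dtype=float)
        gen.transition_observed_ = np.asarray(d["transition_observed"], dtype=bool)
        gen.pools_ = [np.asarray(p, dtype=float) for p in d["pools"]]
        gen.run_success_rates_ = list(d["run_success_rates"])
        gen._build_restricted()
        return gen

    @classmethod
    def from_json(cls, path) -> "ShamScoreGenerator":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# thin functional wrappers -------------------------------------------------


def fit_sham_model(
    nf_scores_by_run: Sequence[Sequence[float]],
    bin_width: float = 10.0,
    estimate_rates: bool = False,
    transition_on: str = "bins",
) -> ShamScoreGenerator:
    """Fit the sham-score model on per-run displayed-score lists."""
    return ShamScoreGenerator(
        bin_width=bin_width, estimate_rates=estimate_rates, transition_on=transition_on
    ).fit(nf_scores_by_run)


def sample_sham_trial(
    model: ShamScoreGenerator,
    run_index: int,
    prev_score: Optional[float],
    rng: np.random.Generator,
) -> float:
    return model.sample_trial(run_index, prev_score, rng)


def generate_sham_session(model: ShamScoreGenerator, rng: np.random.Generator) -> np.ndarray:
    return model.sample_session(rng)
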