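"""Item-response simulator for multi-rater lesion judgements.

Each rater answers each item correctly with probability
``logistic(skill - difficulty)``; the Likert confidence is a deterministic
monotone function of ``|skill - difficulty|``. This gives downstream
agreement statistics a generator with known operating characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ..rater_stats import RaterTable

__all__ = ["RaterModelParams", "simulate_rater_table"]

ANSWER_CATEGORIES = ("benign", "cancer")
DEFAULT_CONFIDENCE_THRESHOLDS = (0.5, 1.5, 2.5, 3.5)


@dataclass
class RaterModelParams:
    """Parameters of the rater-response generator.

    ``difficulty`` (per item) and ``skill`` (per rater) are on the logit
    scale; ``confidence_thresholds`` are the 4 increasing cut points of
    ``|skill - difficulty|`` mapping to Likert levels 1..5.
    """

    n_raters: int
    n_items: int
    difficulty: np.ndarray
    skill: np.ndarray
    truth: list[str]
    confidence_thresholds: tuple[float, ...] = DEFAULT_CONFIDENCE_THRESHOLDS
    grades: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.difficulty = np.broadcast_to(
            np.asarray(self.difficulty, dtype=float), (self.n_items,)
        ).copy()
        self.skill = np.broadcast_to(
            np.asarray(self.skill, dtype=float), (self.n_raters,)
        ).copy()
        if self.n_raters < 1 or self.n_items < 1:
            raise ValueError("need at least one rater and one item")
        if len(self.truth) != self.n_items:
            raise ValueError(
                f"truth has {len(self.truth)} labels for {self.n_items} items"
            )
        bad = set(self.truth) - set(ANSWER_CATEGORIES)
        if bad:
            raise ValueError(f"unknown truth labels {sorted(bad)}")
        th = np.asarray(self.confidence_thresholds, dtype=float)
        if th.shape != (4,) or np.any(np.diff(th) <= 0):
            raise ValueError("confidence_thresholds must be 4 increasing cut points")
        if self.grades is not None and len(self.grades) != self.n_raters:
            raise ValueError("grades must have one entry per rater")

    @property
    def p_correct(self) -> np.ndarray:
        """(n_raters, n_items) matrix of correct-answer probabilities."""
        return expit(self.skill[:, None] - self.difficulty[None, :])

    def to_dict(self) -> dict:
        return {
            "n_raters": self.n_raters,
            "n_items": self.n_items,
            "difficulty": self.difficulty.tolist(),
            "skill": self.skill.tolist(),
            "truth": list(self.truth),
            "confidence_thresholds": list(self.confidence_thresholds),
            "grades": list(self.grades) if self.grades is not None else None,
            "seed": self.seed,
        }


def _confidence_levels(delta: np.ndarray, thresholds: tuple[float, ...]) -> np.ndarray:
    """Monotone map |skill - difficulty| -> Likert 1..5."""
    return 1 + np.searchsorted(np.asarray(thresholds), np.abs(delta), side="right")


def simulate_rater_table(
    params: RaterModelParams, rng: np.random.Generator | None = None
) -> RaterTable:
    """Draw one seeded rater x item answer/confidence table."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params.p_correct
    correct = rng.random(p.shape) < p

    truth = np.asarray(params.truth)
    other = np.where(truth == "cancer", "benign", "cancer")
    answers = np.where(correct, truth[None, :], other[None, :])

    delta = params.skill[:, None] - params.difficulty[None, :]
    confidence = _confidence_levels(delta, params.confidence_thresholds)

    rater_ids = [f"R{i + 1:02d}" for i in range(params.n_raters)]
    item_ids = [f"P{j + 1:02d}" for j in range(params.n_items)]
    grades = params.grades if params.grades is not None else ["unspecified"] * params.n_raters

    return RaterTable(
        answers=pd.DataFrame(answers, index=rater_ids, columns=item_ids),
        confidence=pd.DataFrame(confidence, index=rater_ids, columns=item_ids),
        grades=pd.Series(grades, index=rater_ids, name="grade"),
        truth=pd.Series(truth, index=item_ids, name="pathology"),
    )
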