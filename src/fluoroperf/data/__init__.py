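"""Bundled survey-summary fixtures.

``survey_likert.csv`` is a per-polyp summary of a 32-rater benign/cancer
judgement survey over 14 ambiguous rectal lesions: pathology ground truth,
the majority answer and its percentage share, the mean Likert confidence,
and the 1-5 confidence frequency counts. ``lesion_sizes.csv`` holds mean
rater size estimates vs resected-specimen sizes for the 6 lesions where an
estimate was requested. Cell-level responses were not published, so
vote-count analyses reconstruct counts from the majority percentages.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..rater_stats import AgreementCounts

__all__ = [
    "load_survey_summary",
    "load_lesion_sizes",
    "agreement_counts_from_summary",
    "N_RATERS",
]

N_RATERS = 32


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_survey_summary() -> pd.DataFrame:
    """Per-polyp majority answers, Likert counts and pathology truth."""
    df = _read("survey_likert.csv")
    count_cols = [f"n_{lv}" for lv in range(1, 6)]
    assert (df[count_cols].sum(axis=1) == N_RATERS).all()
    return df


def load_lesion_sizes() -> pd.DataFrame:
    """Mean size estimates (mm) vs actual pathology sizes for 6 lesions."""
    return _read("lesion_sizes.csv")


def agreement_counts_from_summary(summary: pd.DataFrame | None = None) -> AgreementCounts:
    """Reconstruct the per-polyp benign/cancer vote-count matrix.

    The majority share for each polyp is converted back to a vote count via
    ``round(pct * n_raters / 100)`` assigned to the majority answer's
    category (the complement to the other); an "even" majority is a 16/16
    split.
    """
    summary = load_survey_summary() if summary is None else summary
    counts = np.zeros((len(summary), 2), dtype=int)
    for i, row in summary.reset_index(drop=True).iterrows():
        majority = int(round(row["majority_pct"] * N_RATERS / 100.0))
        if row["majority_answer"] == "benign":
            counts[i] = (majority, N_RATERS - majority)
        elif row["majority_answer"] == "cancer":
            counts[i] = (N_RATERS - majority, majority)
        elif row["majority_answer"] == "even":
            counts[i] = (N_RATERS // 2, N_RATERS // 2)
        else:
            raise ValueError(f"unknown majority answer {row['majority_answer']!r}")
    return AgreementCounts(
        counts=counts,
        categories=("benign", "cancer"),
        items=tuple(summary["polyp_id"]),
    )
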