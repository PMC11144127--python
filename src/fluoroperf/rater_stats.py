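"""Multi-rater clinical-judgement analysis.

Implements chance-corrected multi-rater agreement (Fleiss kappa with a
large-sample 95% CI and qualitative interpretation bands), Likert
confidence frequency tables, per-rater and per-group diagnostic accuracy,
majority-vote analysis, Spearman rank correlation, and lesion size
estimation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterTable",
    "AgreementCounts",
    "KappaResult",
    "fleiss_kappa",
    "interpret_kappa",
    "likert_summary",
    "rater_performance",
    "majority_decision",
    "majority_from_counts",
    "spearman_correlation",
    "size_error",
    "build_report",
    "KAPPA_BANDS",
]

ANSWER_CATEGORIES = ("benign", "cancer")
LIKERT_LEVELS = (1, 2, 3, 4, 5)

# (lower, upper, label): closed interval bands for qualitative agreement.
# The published band edges leave gaps (e.g. 0.20-0.21); values in a gap are
# assigned to the lower band with a warning.
KAPPA_BANDS = (
    (-np.inf, 0.20, "poor"),
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "good"),
    (0.81, 1.00, "very good"),
)


class DegenerateAgreementError(ValueError):
    """Expected agreement is 1 (all votes in one category): kappa undefined."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Report-style rounding: halves round away from zero, not to even."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


@dataclass
class RaterTable:
    """Raters x items answer/confidence table with ground truth.

    ``answers`` and ``confidence`` are rater-indexed DataFrames with one
    column per item; ``grades`` maps rater -> grade stratum; ``truth`` maps
    item -> pathology label. ``interest`` and size columns are optional.
    """

    answers: pd.DataFrame
    confidence: pd.DataFrame | None = None
    grades: pd.Series | None = None
    truth: pd.Series | None = None
    interest: pd.Series | None = None
    size_estimates: pd.DataFrame | None = None  # rater x item, mm
    true_sizes: pd.Series | None = None         # item -> mm

    def __post_init__(self) -> None:
        if self.answers.empty:
            raise ValueError("answers table is empty")
        bad = set(np.unique(self.answers.to_numpy().astype(str))) - set(ANSWER_CATEGORIES)
        if bad:
            raise ValueError(f"unknown answer categories {sorted(bad)}")
        if self.confidence is not None:
            if not self.confidence.index.equals(self.answers.index) or not (
                self.confidence.columns.equals(self.answers.columns)
            ):
                raise ValueError("confidence table must align with answers")
            vals = self.confidence.to_numpy()
            if not np.isin(vals, LIKERT_LEVELS).all():
                raise ValueError("confidence values must be integers 1..5")
        if self.truth is not None:
            missing = [c for c in self.answers.columns if c not in self.truth.index]
            if missing:
                raise ValueError(f"truth missing items {missing}")
        if self.grades is not None:
            missing = [r for r in self.answers.index if r not in self.grades.index]
            if missing:
                raise ValueError(f"grades missing raters {missing}")

    @property
    def n_raters(self) -> int:
        return self.answers.shape[0]

    @property
    def n_items(self) -> int:
        return self.answers.shape[1]

    def to_long(self) -> pd.DataFrame:
        """Long-format ``rater_id, grade, polyp_id, answer, confidence``."""
        long = self.answers.stack().rename("answer").reset_index()
        long.columns = ["rater_id", "polyp_id", "answer"]
        if self.confidence is not None:
            conf = self.confidence.stack().rename("confidence").reset_index()
            conf.columns = ["rater_id", "polyp_id", "confidence"]
            long = long.merge(conf, on=["rater_id", "polyp_id"])
        else:
            long["confidence"] = np.nan
        grades = self.grades if self.grades is not None else pd.Series(
            "unspecified", index=self.answers.index
        )
        long.insert(1, "grade", long["rater_id"].map(grades))
        return long[["rater_id", "grade", "polyp_id", "answer", "confidence"]]

    @classmethod
    def from_long(
        cls,
        long: pd.DataFrame,
        truth: pd.DataFrame | None = None,
    ) -> "RaterTable":
        """Build from long CSV records (and optional ``polyp_id, pathology[, size_mm]``)."""
        answers = long.pivot(index="rater_id", columns="polyp_id", values="answer")
        if answers.isna().any().any():
            raise ValueError("missing rater x item cells in long table")
        confidence = None
        if "confidence" in long.columns and long["confidence"].notna().all():
            confidence = long.pivot(
                index="rater_id", columns="polyp_id", values="confidence"
            ).astype(int)
        grades = None
        if "grade" in long.columns:
            grades = long.groupby("rater_id")["grade"].first()
        truth_s = None
        sizes = None
        if truth is not None:
            truth_s = truth.set_index("polyp_id")["pathology"]
            if "size_mm" in truth.columns:
                sizes = truth.set_index("polyp_id")["size_mm"]
        return cls(
            answers=answers, confidence=confidence, grades=grades,
            truth=truth_s, true_sizes=sizes,
        )


@dataclass(frozen=True)
class AgreementCounts:
    """Items x categories vote-count matrix with a constant rater count."""

    counts: np.ndarray
    categories: tuple[str, ...] = ANSWER_CATEGORIES
    items: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("counts must be a 2-D matrix with >= 2 items and >= 2 categories")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise ValueError("every item must have the same number of raters")
        if row_sums[0] < 2:
            raise ValueError("need at least 2 raters per item")

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])

    @classmethod
    def from_table(cls, table: RaterTable) -> "AgreementCounts":
        cats = ANSWER_CATEGORIES
        counts = np.stack(
            [(table.answers == c).sum(axis=0).to_numpy() for c in cats], axis=1
        ).astype(int)
        return cls(counts=counts, categories=cats, items=tuple(table.answers.columns))


@dataclass(frozen=True)
class KappaResult:
    """Fleiss kappa point estimate with large-sample 95% CI."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float
    band: str
    n_items: int
    n_raters: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa, "se": self.se,
            "ci95": [self.ci_low, self.ci_high],
            "p_observed": self.p_observed, "p_expected": self.p_expected,
            "band": self.band, "n_items": self.n_items, "n_raters": self.n_raters,
        }


def fleiss_kappa(counts: AgreementCounts, z: float = 1.959963984540054) -> KappaResult:
    """Fleiss kappa for a fixed rater panel over nominal categories.

    With ``n_ij`` votes for category j on item i, N items and n raters:
    ``P_i = (sum_j n_ij^2 - n) / (n (n - 1))``, ``P_bar = mean_i P_i``,
    ``p_j = sum_i n_ij / (N n)``, ``P_e = sum_j p_j^2`` and
    ``kappa = (P_bar - P_e) / (1 - P_e)``. The standard error uses the
    large-sample form
    ``SE^2 = [2 / (N n (n-1))] [P_e - (2n-3) P_e^2 + 2 (n-2) sum_j p_j^3]
    / (1 - P_e)^2`` and the CI is ``kappa ± z SE``.
    """
    nij = counts.counts.astype(float)
    N, n = counts.n_items, counts.n_raters

    p_i = ((nij**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = nij.sum(axis=0) / (N * n)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0 - 1e-12:
        raise DegenerateAgreementError(
            "degenerate: all votes in a single category, agreement undefined"
        )
    kappa = (p_bar - p_e) / (1 - p_e)
    se2 = (2.0 / (N * n * (n - 1))) * (
        p_e - (2 * n - 3) * p_e**2 + 2 * (n - 2) * (p_j**3).sum()
    ) / (1 - p_e) ** 2
    se = float(np.sqrt(max(se2, 0.0)))
    return KappaResult(
        kappa=float(kappa), se=se,
        ci_low=float(kappa - z * se), ci_high=float(kappa + z * se),
        p_observed=p_bar, p_expected=p_e,
        band=interpret_kappa(float(kappa)),
        n_items=N, n_raters=n,
    )


def interpret_kappa(kappa: float) -> str:
    """Qualitative agreement band for a kappa value.

    Values falling in a gap between published band edges map to the lower
    band with a warning; values below the lowest edge are "poor".
    """
    if kappa > 1 + 1e-12:
        raise ValueError(f"kappa cannot exceed 1, got {kappa}")
    for low, high, label in KAPPA_BANDS:
        if low <= kappa <= high + 1e-12:
            return label
    # in a gap between bands: take the band below
    lower = [b for b in KAPPA_BANDS if b[1] < kappa]
    label = lower[-1][2] if lower else "poor"
    warnings.warn(
        f"kappa {kappa:.4f} falls in a gap of the band table; assigned lower band {label!r}",
        stacklevel=2,
    )
    return label


def likert_summary(table: RaterTable) -> pd.DataFrame:
    """Per-item Likert frequency table with percentages and mean score.

    Returns one row per item with ``n_1..n_5`` counts, ``pct_1..pct_5``,
    the raw mean and the mean rounded to 2 decimals.
    """
    if table.confidence is None:
        raise ValueError("table has no confidence scores")
    rows = []
    n = table.n_raters
    for item in table.confidence.columns:
        col = table.confidence[item]
        counts = {f"n_{lv}": int((col == lv).sum()) for lv in LIKERT_LEVELS}
        mean = float(sum(lv * counts[f"n_{lv}"] for lv in LIKERT_LEVELS) / n)
        row = {"polyp_id": item, **counts}
        row.update({f"pct_{lv}": 100.0 * counts[f"n_{lv}"] / n for lv in LIKERT_LEVELS})
        row["mean_raw"] = mean
        row["mean"] = round_half_up(mean, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("polyp_id")


def _confusion_percentages(answers: pd.Series, truth: pd.Series, positive: str = "cancer") -> dict:
    is_pos = truth == positive
    called_pos = answers == positive
    tp = int((called_pos & is_pos).sum())
    fn = int((~called_pos & is_pos).sum())
    fp = int((called_pos & ~is_pos).sum())
    tn = int((~called_pos & ~is_pos).sum())
    total = tp + fn + fp + tn
    out = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
    out["accuracy"] = 100.0 * (tp + tn) / total if total else np.nan
    out["sensitivity"] = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    out["specificity"] = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    return out


def rater_performance(table: RaterTable) -> dict[str, pd.DataFrame]:
    """Per-rater accuracy/sensitivity/specificity plus grade/interest summaries.

    Group aggregation is the mean of per-rater percentages with min-max
    ranges; groups with zero members are omitted with a warning.
    """
    if table.truth is None:
        raise ValueError("table has no ground-truth pathology")
    truth = table.truth.loc[table.answers.columns]
    per_rater = pd.DataFrame(
        [
            {"rater_id": r, **_confusion_percentages(table.answers.loc[r], truth)}
            for r in table.answers.index
        ]
    ).set_index("rater_id")
    for col in ("accuracy", "sensitivity", "specificity"):
        per_rater[f"{col}_rounded"] = per_rater[col].round(0).astype("Int64")

    groupings: dict[str, pd.Series] = {"all": pd.Series("all", index=table.answers.index)}
    if table.grades is not None:
        groupings["grade"] = table.grades.loc[table.answers.index]
    if table.interest is not None:
        groupings["interest"] = table.interest.loc[table.answers.index].map(
            {True: "complex-polyp interest", False: "no declared interest"}
        )

    summaries = {}
    for name, labels in groupings.items():
        rows = []
        for group, members in labels.groupby(labels):
            idx = members.index
            if len(idx) == 0:  # pragma: no cover - groupby never yields empty
                warnings.warn(f"group {group!r} has no members; omitted")
                continue
            row = {"group": group, "n_raters": len(idx)}
            for col in ("accuracy", "sensitivity", "specificity"):
                vals = per_rater.loc[idx, col]
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_min"] = float(vals.min())
                row[f"{col}_max"] = float(vals.max())
                row[f"{col}_mean_rounded"] = int(round(float(vals.mean())))
            rows.append(row)
        summaries[name] = pd.DataFrame(rows).set_index("group")
    return {"per_rater": per_rater, **summaries}


def majority_decision(table: RaterTable) -> pd.DataFrame:
    """Per-item modal answer with vote share; exact 50/50 splits are "even".

    An even split is flagged and counted as not correct. The returned frame
    carries an ``n_majority_correct`` attribute when truth is available.
    """
    rows = []
    n = table.n_raters
    for item in table.answers.columns:
        col = table.answers[item]
        n_cancer = int((col == "cancer").sum())
        n_benign = n - n_cancer
        if n_cancer == n_benign:
            answer, share, even = "even", 50.0, True
        elif n_cancer > n_benign:
            answer, share, even = "cancer", 100.0 * n_cancer / n, False
        else:
            answer, share, even = "benign", 100.0 * n_benign / n, False
        row = {
            "polyp_id": item, "majority_answer": answer,
            "share_pct": share, "even_split": even,
            "n_benign": n_benign, "n_cancer": n_cancer,
        }
        if table.truth is not None:
            truth = table.truth.loc[item]
            row["truth"] = truth
            row["majority_correct"] = (not even) and (answer == truth)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("polyp_id")
    if table.truth is not None:
        out.attrs["n_majority_correct"] = int(out["majority_correct"].sum())
        out.attrs["n_even"] = int(out["even_split"].sum())
    return out


def majority_from_counts(counts: AgreementCounts, truth) -> pd.DataFrame:
    """Majority analysis straight from a vote-count matrix.

    ``truth`` is one category label per item. Exact ties are flagged
    "even" and counted as not correct, as in :func:`majority_decision`.
    """
    truth = list(truth)
    if len(truth) != counts.n_items:
        raise ValueError("need one truth label per item")
    items = counts.items or tuple(f"item{i}" for i in range(counts.n_items))
    n = counts.n_raters
    rows = []
    for i, item in enumerate(items):
        row_counts = counts.counts[i]
        top = int(row_counts.max())
        winners = [counts.categories[j] for j in np.flatnonzero(row_counts == top)]
        even = len(winners) > 1
        answer = "even" if even else winners[0]
        rows.append(
            {
                "polyp_id": item,
                "majority_answer": answer,
                "share_pct": 100.0 * top / n,
                "even_split": even,
                "truth": truth[i],
                "majority_correct": (not even) and answer == truth[i],
            }
        )
    out = pd.DataFrame(rows).set_index("polyp_id")
    out.attrs["n_majority_correct"] = int(out["majority_correct"].sum())
    out.attrs["n_even"] = int(out["even_split"].sum())
    return out


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties and a t-approximation p-value.

    Raises on zero variance in either series (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def size_error(
    estimates: pd.Series, actual: pd.Series, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Signed and absolute percent size-estimation error per item.

    ``signed_pct = (estimate - actual) / actual * 100``. The returned frame
    carries mean signed/absolute errors in ``attrs``; when ``groups`` is
    given, per-group means are included as well.
    """
    actual = actual.loc[estimates.index]
    if (actual <= 0).any():
        bad = actual.index[actual <= 0].tolist()
        raise ValueError(f"actual size must be positive; offending items: {bad}")
    signed = (estimates - actual) / actual * 100.0
    out = pd.DataFrame(
        {
            "estimate_mm": estimates,
            "actual_mm": actual,
            "signed_pct": signed,
            "abs_pct": signed.abs(),
        }
    )
    out.attrs["mean_signed_pct"] = float(signed.mean())
    out.attrs["mean_abs_pct"] = float(signed.abs().mean())
    if groups is not None:
        out["group"] = groups.loc[estimates.index]
        out.attrs["group_mean_abs_pct"] = (
            out.groupby("group")["abs_pct"].mean().to_dict()
        )
    return out


def build_report(table: RaterTable) -> dict:
    """Consolidated JSON-serializable rater-statistics report."""
    report: dict = {"n_raters": table.n_raters, "n_items": table.n_items}

    counts = AgreementCounts.from_table(table)
    try:
        report["kappa"] = fleiss_kappa(counts).to_dict()
    except DegenerateAgreementError as exc:
        report["kappa"] = {"error": str(exc)}

    if table.confidence is not None:
        report["likert"] = likert_summary(table).reset_index().to_dict(orient="records")

    if table.truth is not None:
        perf = rater_performance(table)
        report["performance"] = {
            name: df.reset_index().to_dict(orient="records")
            for name, df in perf.items()
            if name != "per_rater"
        }
        maj = majority_decision(table)
        report["majority"] = {
            "per_item": maj.reset_index().to_dict(orient="records"),
            "n_majority_correct": maj.attrs["n_majority_correct"],
            "n_even": maj.attrs["n_even"],
        }
        if table.confidence is not None:
            truth_mat = pd.DataFrame(
                np.broadcast_to(
                    table.truth.loc[table.answers.columns].to_numpy()[None, :],
                    table.answers.shape,
                ),
                index=table.answers.index,
                columns=table.answers.columns,
            )
            correct = (table.answers == truth_mat).to_numpy().ravel().astype(float)
            conf = table.confidence.to_numpy().ravel().astype(float)
            try:
                rho, p = spearman_correlation(conf, correct)
                report["confidence_vs_correct"] = {"rho": rho, "p": p}
            except ValueError as exc:
                report["confidence_vs_correct"] = {"error": str(exc)}

    if table.true_sizes is not None and table.size_estimates is not None:
        est = table.size_estimates.mean(axis=0)
        err = size_error(est, table.true_sizes.loc[est.index])
        report["size_error"] = {
            "per_item": err.reset_index(names="polyp_id").to_dict(orient="records"),
            "mean_signed_pct": err.attrs["mean_signed_pct"],
            "mean_abs_pct": err.attrs["mean_abs_pct"],
        }
    return report
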