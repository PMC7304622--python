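"""Model-versus-reader agreement statistics for age estimation.

The precision statistic standard in the age-reading literature is the
coefficient of variation (CV) between independent estimates of the same
specimen.  Here the two estimates are the human read age and the model
prediction: per otolith,

    CV = 100 * sd(read, predicted) / mean(read, predicted),

with the two-reading sample standard deviation (n-1 denominator, i.e.
|a - b| / sqrt(2)).  Per age group and data variant the mean CV over
specimens is reported after excluding outliers with the 1.5 x IQR rule
(quartiles by linear interpolation).  RMSE between read and predicted
age summarizes overall accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .groups import GROUP_ORDER, assign_age_group


@dataclass(frozen=True)
class AgePair:
    """One otolith's human read age and model-predicted age."""

    read_age: int
    predicted_age: int
    sample_id: str = ""
    variant: str = "baseline"
    split: str = "train"

    def __post_init__(self) -> None:
        for a in (self.read_age, self.predicted_age):
            if not (1 <= a <= 26):
                raise ValueError(f"ages must be in [1, 26], got {a}")


def rmse(pairs: list[AgePair]) -> float:
    """Root mean squared error between predicted and read ages."""
    if not pairs:
        raise ValueError("rmse of an empty list is undefined")
    d = np.array([p.predicted_age - p.read_age for p in pairs], dtype=float)
    return float(np.sqrt(np.mean(d ** 2)))


def pairwise_cv(read_age: float, predicted_age: float, ddof: int = 1) -> float:
    """Percent CV of the two independent age estimates of one otolith.

    ``ddof=1`` (default) is the two-reading sample standard deviation,
    |a - b|/sqrt(2); ``ddof=0`` gives the population form |a - b|/2.
    """
    a, b = float(read_age), float(predicted_age)
    mean = (a + b) / 2.0
    if mean == 0:
        raise ValueError("mean age of zero is impossible for ages >= 1")
    sd = abs(a - b) / (np.sqrt(2.0) if ddof == 1 else 2.0)
    return 100.0 * sd / mean


def iqr_filter(values: list[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1.5 x IQR outlier exclusion with linear-interpolation quartiles.

    Returns ``(kept, excluded)``; with fewer than 4 values no exclusion
    is performed (a warning is emitted).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        if values.size:
            warnings.warn("fewer than 4 values: IQR rule not applied",
                          stacklevel=2)
        return values, np.array([])
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


@dataclass
class CVSummary:
    """Mean CV for one age group / variant / split after IQR exclusion."""

    group: str
    variant: str
    split: str
    n: int
    n_excluded: int
    per_sample_cv: np.ndarray
    excluded_ids: list[str]
    mean_cv: float  # nan when the group is empty after filtering


def mean_cv_by_group(pairs: list[AgePair], variant: str | None = None,
                     split: str | None = None, ddof: int = 1,
                     group_by: str = "read") -> list[CVSummary]:
    """Per-group mean CV with 1.5 x IQR outlier exclusion.

    Group membership is assigned from the human read age by default
    (``group_by="read"``; the grouping is a property of the specimen),
    switchable to the model prediction with ``group_by="predicted"``.
    """
    if group_by not in ("read", "predicted"):
        raise ValueError("group_by must be 'read' or 'predicted'")
    selected = [p for p in pairs
                if (variant is None or p.variant == variant)
                and (split is None or p.split == split)]
    summaries = []
    for group in GROUP_ORDER:
        members = [
            p for p in selected
            if assign_age_group(p.read_age if group_by == "read"
                                else p.predicted_age) == group
        ]
        cvs = np.array([pairwise_cv(p.read_age, p.predicted_age, ddof=ddof)
                        for p in members])
        if cvs.size == 0:
            summaries.append(CVSummary(
                group=group, variant=variant or "all", split=split or "all",
                n=0, n_excluded=0, per_sample_cv=cvs, excluded_ids=[],
                mean_cv=float("nan")))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept, excluded = iqr_filter(cvs)
        excl_mask = np.zeros(len(cvs), dtype=bool)
        if excluded.size:
            q1, q3 = np.percentile(cvs, [25, 75], method="linear")
            iqr = q3 - q1
            excl_mask = (cvs < q1 - 1.5 * iqr) | (cvs > q3 + 1.5 * iqr)
        excluded_ids = [m.sample_id for m, e in zip(members, excl_mask) if e]
        summaries.append(CVSummary(
            group=group, variant=variant or "all", split=split or "all",
            n=len(members), n_excluded=len(excluded_ids),
            per_sample_cv=cvs, excluded_ids=excluded_ids,
            mean_cv=float(np.mean(kept)) if kept.size else float("nan")))
    return summaries
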