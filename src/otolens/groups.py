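"""Age groups and per-age average relevance maps.

Greenland halibut ages 1-26 are partitioned into four morphological
groups: juveniles (1-4), adolescents (5-9), young adults (10-13) and
adults (14-26).  Average relevance maps summarize, per predicted age,
where the network focuses; each average is normalized by its maximum so
panels are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spray import HeatmapDescriptor

AGE_GROUPS: dict[str, tuple[int, int]] = {
    "juvenile": (1, 4),
    "adolescent": (5, 9),
    "young_adult": (10, 13),
    "adult": (14, 26),
}

GROUP_ORDER = tuple(AGE_GROUPS)

#: consecutive pairs analyzed together in the clustering experiments
CONSECUTIVE_PAIRS = (
    ("juvenile", "adolescent"),
    ("adolescent", "young_adult"),
    ("young_adult", "adult"),
)


def assign_age_group(age: int) -> str:
    """The unique group containing ``age`` (1-26)."""
    for name, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return name
    raise ValueError(f"age must be in [1, 26], got {age}")


@dataclass
class AverageMap:
    grid: np.ndarray  # 56x56, max-normalized to 1 when the mean is nonzero
    predicted_age: int
    n_samples: int
    variant: str
    normalized: bool  # False when the mean map was all zero


def average_relevance_map(descriptors: list[HeatmapDescriptor]) -> AverageMap:
    """Element-wise mean of the descriptors for one predicted age,
    normalized by its maximum."""
    if not descriptors:
        raise ValueError("cannot average an empty list of descriptors")
    ages = {d.predicted_age for d in descriptors}
    variants = {d.variant for d in descriptors}
    if len(ages) != 1 or len(variants) != 1:
        raise ValueError("descriptors must share predicted_age and variant")
    mean = np.mean([d.grid for d in descriptors], axis=0)
    peak = float(mean.max())
    normalized = peak > 0
    if normalized:
        mean = mean / peak
    return AverageMap(grid=mean, predicted_age=ages.pop(),
                      n_samples=len(descriptors), variant=variants.pop(),
                      normalized=normalized)


def select_display_ages(counts: dict[int, int], group: str,
                        max_ages: int = 4) -> list[int]:
    """The (up to) ``max_ages`` ages within ``group`` with the most
    predictions; ties broken toward the lower age."""
    lo, hi = AGE_GROUPS[group]
    candidates = [(age, n) for age, n in counts.items()
                  if lo <= age <= hi and n > 0]
    candidates.sort(key=lambda an: (-an[1], an[0]))
    return [age for age, _ in candidates[:max_ages]]
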