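"""Single-division meiotic mutation rate from matched frequency pairs.

The meiotic rate is the median, over cultures, of the post-sporulation
mutant frequency minus the pre-sporulation (mitotic) mutant frequency;
meiosis is a single division, so the median frequency difference is
itself a per-division rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MeiosisPair",
    "RateComparison",
    "meiotic_rate",
    "fold_change",
    "rate_ttest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeiosisPair:
    """Matched mitotic and meiotic mutant frequencies for one culture."""

    culture_id: str
    mitotic_frequency: float
    meiotic_frequency: float

    def __post_init__(self) -> None:
        for name in ("mitotic_frequency", "meiotic_frequency"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")

    @property
    def difference(self) -> float:
        return self.meiotic_frequency - self.mitotic_frequency


@dataclass(frozen=True)
class RateComparison:
    """A pair of per-division rates and their fold ratio."""

    numerator_rate: float
    denominator_rate: float

    def __post_init__(self) -> None:
        if self.denominator_rate <= 0:
            raise ValueError("denominator rate must be positive")

    @property
    def fold(self) -> float:
        return self.numerator_rate / self.denominator_rate


def meiotic_rate(pairs: Sequence[MeiosisPair]) -> float:
    """Median over cultures of (meiotic - mitotic) frequency.

    Negative per-culture differences are retained — flooring them at zero
    would bias the median upward; a warning is logged when more than 25%
    of differences are negative.  Even-length medians are midpoints.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one frequency pair")
    diffs = np.array([p.difference for p in pairs])
    neg = float(np.mean(diffs < 0))
    if neg > 0.25:
        logger.warning(
            "%.0f%% of per-culture differences are negative; check that "
            "sporulation actually elevated the mutant frequency",
            100 * neg,
        )
    return float(np.median(diffs))


def fold_change(meiotic: float, mitotic: float) -> float:
    """Ratio of meiotic to mitotic rate (report rounded to one decimal)."""
    if mitotic <= 0:
        raise ValueError("mitotic rate must be positive")
    return meiotic / mitotic


def rate_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t test on per-culture differences.

    Welch's (unequal variance) variant by default; pass
    ``equal_var=True`` for the pooled-variance Student variant.
    Returns (statistic, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
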