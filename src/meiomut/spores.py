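"""Random-spore crossover analysis.

Classifies each spore's ordered parental-origin calls into exchanged
intervals, tallies crossover classes (none / single / double / triple),
computes expected multiple-crossover percentages under independence and
observed/expected interference ratios, and compares groups of spores
(e.g. mutant vs non-mutant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._stats import pooled_chi2_contingency

__all__ = [
    "SporeRecord",
    "CrossoverTally",
    "UnknownCallError",
    "classify_spore",
    "tally_spores",
    "expected_multi_co",
    "observed_multi_co",
    "interference_ratio",
    "compare_groups",
    "GroupComparison",
]

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset({"P1", "P2"})


class UnknownCallError(ValueError):
    """Raised when a spore carries a marker call other than P1/P2."""


@dataclass(frozen=True)
class SporeRecord:
    """One random spore: ordered parental-origin calls plus selection state.

    ``marker_calls`` must already be phased to parental origin (values
    ``"P1"``/``"P2"``), ordered by chromosome position.
    """

    spore_id: str
    marker_calls: tuple[str, ...]
    canavanine: str = "sensitive"
    ade2_red: bool = True
    cyh_resistant: bool = True

    def __post_init__(self) -> None:
        if self.canavanine not in ("resistant", "sensitive"):
            raise ValueError(f"canavanine must be resistant/sensitive, got {self.canavanine!r}")


def classify_spore(spore: SporeRecord) -> frozenset[int]:
    """Intervals (0-based index ``i`` = markers ``i``..``i+1``) with an exchange.

    An interval is exchanged iff the adjacent calls differ.  The empty set
    means a non-crossover spore.  Multi-exchange spores may in truth be
    gene conversions of internal markers; this ambiguity cannot be
    resolved from the calls and is surfaced via
    :attr:`CrossoverTally.ambiguous_gc` downstream.
    """
    calls = spore.marker_calls
    if len(calls) < 2:
        raise ValueError("need at least 2 markers to classify a spore")
    bad = set(calls) - VALID_CALLS
    if bad:
        raise UnknownCallError(
            f"spore {spore.spore_id!r} has unknown call(s): {sorted(bad)}"
        )
    return frozenset(i for i in range(len(calls) - 1) if calls[i] != calls[i + 1])


@dataclass
class CrossoverTally:
    """Per-interval and per-class crossover tallies for a group of spores."""

    n_intervals: int
    total: int
    per_interval: np.ndarray
    class_counts: dict[frozenset[int], int]
    n_excluded: int = 0

    @property
    def n_nco(self) -> int:
        return self.class_counts.get(frozenset(), 0)

    def n_with_exactly(self, k: int) -> int:
        """Spores with exactly ``k`` exchanged intervals."""
        return sum(n for cls, n in self.class_counts.items() if len(cls) == k)

    @property
    def ambiguous_gc(self) -> int:
        """Multi-exchange spores: indistinguishable from gene conversions."""
        return sum(n for cls, n in self.class_counts.items() if len(cls) >= 2)

    def marginal_fraction(self, interval: int) -> float:
        """Fraction of spores exchanged in ``interval`` (multis included)."""
        if self.total == 0:
            raise ValueError("empty tally")
        return float(self.per_interval[interval]) / self.total


def tally_spores(spores: Iterable[SporeRecord]) -> CrossoverTally:
    """Tally crossover classes; spores with unknown calls are excluded."""
    class_counts: dict[frozenset[int], int] = {}
    per_interval: np.ndarray | None = None
    total = 0
    excluded = 0
    n_intervals = 0
    for spore in spores:
        try:
            exchanged = classify_spore(spore)
        except UnknownCallError as exc:
            excluded += 1
            logger.debug("excluded spore: %s", exc)
            continue
        k = len(spore.marker_calls) - 1
        if per_interval is None:
            n_intervals = k
            per_interval = np.zeros(k, dtype=np.int64)
        elif k != n_intervals:
            raise ValueError("all spores must share the same marker set")
        total += 1
        class_counts[exchanged] = class_counts.get(exchanged, 0) + 1
        for i in exchanged:
            per_interval[i] += 1
    if per_interval is None:
        raise ValueError("no classifiable spores")
    if excluded:
        logger.info("%d spore(s) excluded for unknown marker calls", excluded)
    return CrossoverTally(
        n_intervals=n_intervals,
        total=total,
        per_interval=per_interval,
        class_counts=class_counts,
        n_excluded=excluded,
    )


def expected_multi_co(tally: CrossoverTally, intervals: Sequence[int]) -> float:
    """Expected percent of spores exchanged in every listed interval.

    Product rule over the marginal crossover fractions of the intervals
    (marginals include spores with multiple crossovers).
    """
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    frac = 1.0
    for i in intervals:
        frac *= tally.marginal_fraction(i)
    return 100.0 * frac


def observed_multi_co(tally: CrossoverTally, intervals: Sequence[int]) -> float:
    """Observed percent of spores exchanged in every listed interval."""
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    want = set(intervals)
    n = sum(c for cls, c in tally.class_counts.items() if want <= cls)
    return 100.0 * n / tally.total


def interference_ratio(observed_pct: float, expected_pct: float) -> float:
    """Observed/expected multiple-crossover ratio; < 1 means interference.

    Returns NaN (with a log message) when both are 0, and +inf when the
    expectation is 0 but crossovers were observed.
    """
    if expected_pct < 0 or observed_pct < 0:
        raise ValueError("percentages must be >= 0")
    if expected_pct == 0:
        if observed_pct == 0:
            logger.warning("interference ratio undefined: expected and observed are 0")
            return float("nan")
        logger.warning("expected 0 with observed > 0: ratio flagged infinite")
        return float("inf")
    return observed_pct / expected_pct


@dataclass(frozen=True)
class GroupComparison:
    """Per-interval crossover-fraction ratios (a/b) with chi-square tests."""

    ratios: tuple[float, ...]
    chisq: tuple[tuple[float, float], ...]  # (statistic, p) per interval

    @property
    def p_values(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.chisq)


def compare_groups(a: CrossoverTally, b: CrossoverTally) -> GroupComparison:
    """Compare per-interval crossover fractions between two spore groups.

    For each interval the fold ratio ``fraction(a)/fraction(b)`` is
    reported (NaN-flagged when the denominator fraction is 0), together
    with a Pearson chi-square on the crossover/no-crossover 2x2 table.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both groups must be nonempty")
    if a.n_intervals != b.n_intervals:
        raise ValueError("groups must share the same interval structure")
    ratios = []
    tests = []
    for i in range(a.n_intervals):
        fa = a.marginal_fraction(i)
        fb = b.marginal_fraction(i)
        if fb == 0:
            logger.warning("interval %d: zero denominator fraction; ratio is NaN", i)
            ratios.append(float("nan"))
        else:
            ratios.append(fa / fb)
        table = np.array(
            [
                [a.per_interval[i], a.total - a.per_interval[i]],
                [b.per_interval[i], b.total - b.per_interval[i]],
            ],
            dtype=float,
        )
        try:
            stat, _, p = pooled_chi2_contingency(table)
        except ValueError:
            stat, p = float("nan"), float("nan")
        tests.append((stat, p))
    return GroupComparison(ratios=tuple(ratios), chisq=tuple(tests))
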