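"""Tetrad analysis: PD/NPD/TT classification and Perkins map distances."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import pooled_chi2_contingency

__all__ = [
    "GeneConversionError",
    "TetradGenotypes",
    "TetradCounts",
    "classify_tetrad",
    "tally_tetrads",
    "perkins_cm",
    "percent_recombination",
    "perkins_se",
    "cm_per_kb",
    "chisq_tetrads",
    "summarize_intervals",
]

logger = logging.getLogger(__name__)


class GeneConversionError(ValueError):
    """Raised when a marker does not segregate 2:2 within a tetrad."""


@dataclass(frozen=True)
class TetradGenotypes:
    """Genotype calls for the four spores of one dissected tetrad."""

    tetrad_id: str
    spores: tuple[tuple[str, ...], ...]
    marker_order: tuple[str, ...]
    parental_haplotypes: tuple[tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise ValueError(f"tetrad {self.tetrad_id!r} must have exactly 4 spores")
        k = len(self.marker_order)
        for spore in self.spores:
            if len(spore) != k:
                raise ValueError("spore genotype length must match marker_order")
        if len(self.parental_haplotypes) != 2:
            raise ValueError("exactly 2 parental haplotypes required")

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_order.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None


@dataclass
class TetradCounts:
    """PD/NPD/TT tallies for one marker interval."""

    interval: tuple[str, str]
    pd: int
    npd: int
    tt: int
    kb: float | None = None

    def __post_init__(self) -> None:
        if min(self.pd, self.npd, self.tt) < 0:
            raise ValueError("tetrad class counts must be >= 0")

    @property
    def total(self) -> int:
        return self.pd + self.npd + self.tt


def classify_tetrad(tetrad: TetradGenotypes, interval: tuple[str, str]) -> str:
    """Classify one tetrad for a marker pair as ``"PD"``, ``"NPD"`` or ``"TT"``.

    Each spore is parental if its two calls match a single parental
    haplotype, recombinant otherwise.  Non-2:2 segregation at either
    marker raises :class:`GeneConversionError`.
    """
    i = tetrad.marker_index(interval[0])
    j = tetrad.marker_index(interval[1])
    parents = tetrad.parental_haplotypes
    for idx in (i, j):
        alleles = [s[idx] for s in tetrad.spores]
        allowed = {parents[0][idx], parents[1][idx]}
        extra = set(alleles) - allowed
        if extra:
            raise GeneConversionError(
                f"tetrad {tetrad.tetrad_id!r}: non-parental allele(s) {extra} "
                f"at marker {tetrad.marker_order[idx]!r}"
            )
        if alleles.count(parents[0][idx]) != 2:
            raise GeneConversionError(
                f"tetrad {tetrad.tetrad_id!r}: non-2:2 segregation at marker "
                f"{tetrad.marker_order[idx]!r}"
            )
    parental_pairs = {(p[i], p[j]) for p in parents}
    n_parental = sum((s[i], s[j]) in parental_pairs for s in tetrad.spores)
    if n_parental == 4:
        return "PD"
    if n_parental == 0:
        return "NPD"
    if n_parental == 2:
        return "TT"
    # 1 or 3 parental spore pairs is impossible under 2:2 segregation
    raise GeneConversionError(
        f"tetrad {tetrad.tetrad_id!r}: inconsistent segregation for {interval}"
    )


def tally_tetrads(
    tetrads: Iterable[TetradGenotypes],
    interval: tuple[str, str],
    kb: float | None = None,
) -> tuple[TetradCounts, int]:
    """Tally PD/NPD/TT over tetrads; gene-conversion tetrads are excluded.

    Returns the counts plus the number of excluded (non-2:2) tetrads.
    """
    counts = {"PD": 0, "NPD": 0, "TT": 0}
    n_gc = 0
    for tetrad in tetrads:
        try:
            counts[classify_tetrad(tetrad, interval)] += 1
        except GeneConversionError as exc:
            n_gc += 1
            logger.debug("excluded tetrad: %s", exc)
    if n_gc:
        logger.info(
            "%d tetrad(s) excluded from %s as gene conversions", n_gc, interval
        )
    return (
        TetradCounts(interval=interval, pd=counts["PD"], npd=counts["NPD"], tt=counts["TT"], kb=kb),
        n_gc,
    )


def perkins_cm(counts: TetradCounts) -> float:
    """Perkins map distance: cM = 50 (T + 6 NPD) / (PD + NPD + TT)."""
    n = counts.total
    if n == 0:
        raise ValueError("cannot compute a map distance from zero tetrads")
    return 50.0 * (counts.tt + 6.0 * counts.npd) / n


def percent_recombination(counts: TetradCounts) -> float:
    """Percent recombinant spores: 100 (T + 2 NPD) / (PD + NPD + TT)."""
    n = counts.total
    if n == 0:
        raise ValueError("cannot compute recombination from zero tetrads")
    return 100.0 * (counts.tt + 2.0 * counts.npd) / n


def perkins_se(counts: TetradCounts) -> float:
    """Standard error of the Perkins distance, in cM.

    SE = (100 / 2n) * sqrt(T + 36 NPD - (T + 6 NPD)^2 / n).
    """
    n = counts.total
    if n <= 1:
        raise ValueError("need at least 2 tetrads for a standard error")
    inner = counts.tt + 36.0 * counts.npd - (counts.tt + 6.0 * counts.npd) ** 2 / n
    return (100.0 / (2.0 * n)) * math.sqrt(max(inner, 0.0))


def cm_per_kb(cm: float, kb: float) -> float:
    """Recombination density over the homologous portion of the interval."""
    if kb <= 0:
        raise ValueError("kb must be positive")
    return cm / kb


def chisq_tetrads(a: TetradCounts, b: TetradCounts) -> tuple[float, int, float]:
    """Pearson chi-square comparing PD/NPD/TT proportions of two strains.

    Cells with expected counts below 5 are pooled (NPD into TT first);
    all-zero columns are dropped.  Returns (statistic, df, p).
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both count tables must be nonempty")
    table = np.array([[a.pd, a.npd, a.tt], [b.pd, b.npd, b.tt]], dtype=float)
    return pooled_chi2_contingency(table)


def summarize_intervals(
    counts: Sequence[TetradCounts], precision: int = 1
) -> pd.DataFrame:
    """Table of PD/NPD/TT, % recombination, cM +/- SE, kb and cM/kb."""
    rows = []
    for c in counts:
        cm = perkins_cm(c)
        row = {
            "interval": f"{c.interval[0]}-{c.interval[1]}",
            "PD": c.pd,
            "NPD": c.npd,
            "TT": c.tt,
            "pct_recombination": round(percent_recombination(c), precision),
            "cM": round(cm, precision),
            "cM_se": round(perkins_se(c), precision) if c.total > 1 else float("nan"),
            "kb": c.kb,
            "cM_per_kb": round(cm_per_kb(cm, c.kb), 2) if c.kb else float("nan"),
        }
        rows.append(row)
    return pd.DataFrame(rows)
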