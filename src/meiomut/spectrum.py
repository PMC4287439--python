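"""Mutation-spectrum classification and positional distribution tests."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._stats import pooled_chi2_contingency

__all__ = [
    "MutationRecord",
    "SpectrumSummary",
    "classify_mutation",
    "classify_isolate",
    "summarize_spectrum",
    "compare_spectra",
    "positional_distribution",
]

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MutationRecord:
    """One sequenced mutation: position is 1-based from the ORF start (A of ATG = +1)."""

    isolate_id: str
    position: int
    ref: str
    alt: str
    phase_label: str = "mitosis"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for name, seq in (("ref", self.ref), ("alt", self.alt)):
            if set(seq) - BASES:
                raise ValueError(f"{name} must be over ACGT, got {seq!r}")


def classify_mutation(record: MutationRecord) -> tuple[str, str | None]:
    """Class of a single mutation record.

    Returns ``(major, minor)``:

    * single-base change -> ``("substitution", "transition"|"transversion")``
    * length change not a multiple of 3 -> ``("frameshift", "contraction"|"expansion")``
    * nonzero length change divisible by 3 -> ``("in_frame_indel", None)``
    * equal-length multi-base change -> ``("complex", None)``
    """
    dlen = len(record.alt) - len(record.ref)
    if dlen == 0:
        if len(record.ref) == 1:
            both = {record.ref, record.alt}
            minor = "transition" if both <= PURINES or both <= PYRIMIDINES else "transversion"
            return "substitution", minor
        return "complex", None
    if abs(dlen) % 3 == 0:
        return "in_frame_indel", None
    return "frameshift", "contraction" if dlen < 0 else "expansion"


def classify_isolate(records: Sequence[MutationRecord]) -> tuple[str, str | None]:
    """Class of one isolate: complex when it carries >= 2 distinct mutations."""
    if not records:
        raise ValueError("isolate must carry at least one mutation")
    if len(records) >= 2:
        return "complex", None
    return classify_mutation(records[0])


@dataclass(frozen=True)
class SpectrumSummary:
    """Isolate-level class counts for one group (phase)."""

    n_total: int
    n_frameshift: int
    n_contraction: int
    n_expansion: int
    n_substitution: int
    n_transition: int
    n_transversion: int
    n_complex: int
    n_in_frame_indel: int = 0

    def __post_init__(self) -> None:
        if self.n_contraction + self.n_expansion != self.n_frameshift:
            raise ValueError("contraction + expansion must equal frameshift count")
        if self.n_transition + self.n_transversion != self.n_substitution:
            raise ValueError("transition + transversion must equal substitution count")
        parts = (
            self.n_frameshift + self.n_substitution + self.n_complex + self.n_in_frame_indel
        )
        if parts != self.n_total:
            raise ValueError("class counts must sum to n_total")

    def percent(self, klass: str) -> int:
        """Class percentage rounded to the nearest integer."""
        count = getattr(self, f"n_{klass}")
        return round(100.0 * count / self.n_total)


def summarize_spectrum(
    records: Iterable[MutationRecord],
) -> dict[str, SpectrumSummary]:
    """Per-phase isolate-level spectrum summaries."""
    by_phase: dict[str, dict[str, list[MutationRecord]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for rec in records:
        by_phase[rec.phase_label][rec.isolate_id].append(rec)
    if not by_phase:
        raise ValueError("no mutation records supplied")
    out = {}
    for phase, isolates in by_phase.items():
        counts: dict[tuple[str, str | None], int] = defaultdict(int)
        for recs in isolates.values():
            counts[classify_isolate(recs)] += 1
        out[phase] = SpectrumSummary(
            n_total=sum(counts.values()),
            n_frameshift=counts[("frameshift", "contraction")]
            + counts[("frameshift", "expansion")],
            n_contraction=counts[("frameshift", "contraction")],
            n_expansion=counts[("frameshift", "expansion")],
            n_substitution=counts[("substitution", "transition")]
            + counts[("substitution", "transversion")],
            n_transition=counts[("substitution", "transition")],
            n_transversion=counts[("substitution", "transversion")],
            n_complex=counts[("complex", None)],
            n_in_frame_indel=counts[("in_frame_indel", None)],
        )
    return out


def compare_spectra(
    a: SpectrumSummary, b: SpectrumSummary, mode: str = "frameshift"
) -> tuple[float, float]:
    """Chi-square comparison of two spectra.

    ``mode="frameshift"``: 2x2 on frameshift vs everything else.
    ``mode="full"``: frameshift / substitution / complex (complex pooled
    when expected counts are small).  Returns (statistic, p).
    """
    if a.n_total == 0 or b.n_total == 0:
        raise ValueError("both groups must be nonempty")
    if mode == "frameshift":
        table = np.array(
            [
                [a.n_frameshift, a.n_total - a.n_frameshift],
                [b.n_frameshift, b.n_total - b.n_frameshift],
            ],
            dtype=float,
        )
    elif mode == "full":
        table = np.array(
            [
                [a.n_frameshift, a.n_substitution, a.n_complex],
                [b.n_frameshift, b.n_substitution, b.n_complex],
            ],
            dtype=float,
        )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    stat, _, p = pooled_chi2_contingency(table)
    return stat, p


def window_index(position: int, window_bp: int = 200) -> int:
    """0-based window of a 1-based position; windows are [1,201), [201,401), ..."""
    return (position - 1) // window_bp


def positional_distribution(
    groups: Mapping[str, Sequence[MutationRecord]],
    orf_length: int,
    window_bp: int = 200,
) -> tuple[dict[str, np.ndarray], float]:
    """Per-window mutation counts per group + chi-square homogeneity p.

    Records with positions beyond the ORF are flagged and excluded.
    Windows with small expected counts are pooled before the test.
    """
    if orf_length < 1:
        raise ValueError("orf_length must be >= 1")
    n_windows = (orf_length + window_bp - 1) // window_bp
    counts: dict[str, np.ndarray] = {}
    for name, records in groups.items():
        c = np.zeros(n_windows, dtype=np.int64)
        for rec in records:
            if rec.position > orf_length:
                logger.warning(
                    "record %s at %d beyond ORF (%d bp): excluded",
                    rec.isolate_id,
                    rec.position,
                    orf_length,
                )
                continue
            c[window_index(rec.position, window_bp)] += 1
        counts[name] = c
    if len(counts) != 2:
        raise ValueError("homogeneity test requires exactly 2 groups")
    table = np.vstack(list(counts.values())).astype(float)
    _, _, p = pooled_chi2_contingency(table)
    return counts, p
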