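"""Readers and writers for the TSV dialects used across the package.

All tables are UTF-8 tab-separated with a header row; lines starting
with ``#`` are comments.  Counts are whole-culture equivalents — any
dilution or plating scaling must happen upstream.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .fluctuation import CultureObservation, FluctuationExperiment
from .meiotic import MeiosisPair
from .spectrum import MutationRecord
from .spores import SporeRecord
from .tetrads import TetradGenotypes

__all__ = [
    "read_cultures",
    "read_pairs",
    "read_tetrads",
    "read_spores",
    "read_mutations",
    "read_interval_config",
    "read_phase_config",
    "write_tsv",
]

logger = logging.getLogger(__name__)

PARENT_IDS = ("parental_1", "parental_2")


def _read_table(path: str | Path, dtype: Mapping[str, type] | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=dtype)


def read_cultures(path: str | Path, label: str = "") -> FluctuationExperiment:
    """Read `culture_id  mutant_count  total_cells` rows."""
    df = _read_table(path)
    required = {"culture_id", "mutant_count", "total_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    cultures = [
        CultureObservation(
            culture_id=str(row.culture_id),
            mutant_count=int(row.mutant_count),
            total_cells=int(row.total_cells),
        )
        for row in df.itertuples()
    ]
    return FluctuationExperiment(cultures=cultures, label=label or str(path))


def read_pairs(path: str | Path) -> list[MeiosisPair]:
    """Read matched mitotic/meiotic counts; frequencies are computed here."""
    df = _read_table(path)
    required = {
        "culture_id",
        "mitotic_mutants",
        "mitotic_total",
        "meiotic_mutants",
        "meiotic_total",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        MeiosisPair(
            culture_id=str(row.culture_id),
            mitotic_frequency=row.mitotic_mutants / row.mitotic_total,
            meiotic_frequency=row.meiotic_mutants / row.meiotic_total,
        )
        for row in df.itertuples()
    ]


def read_tetrads(path: str | Path) -> list[TetradGenotypes]:
    """Read `tetrad_id  spore_index  marker...` rows.

    The two parental haplotypes come first, as rows with ``tetrad_id``
    ``parental_1`` and ``parental_2`` (their ``spore_index`` is ignored).
    Every other tetrad_id must appear on exactly 4 rows.
    """
    df = _read_table(path, dtype=str)
    if df.columns[0] != "tetrad_id" or df.columns[1] != "spore_index":
        raise ValueError(f"{path}: first two columns must be tetrad_id, spore_index")
    markers = tuple(df.columns[2:])
    if len(markers) < 2:
        raise ValueError(f"{path}: need at least 2 marker columns")
    parents = {}
    for pid in PARENT_IDS:
        rows = df[df.tetrad_id == pid]
        if len(rows) != 1:
            raise ValueError(f"{path}: expected exactly one {pid} row")
        parents[pid] = tuple(rows.iloc[0][list(markers)])
    tetrads = []
    body = df[~df.tetrad_id.isin(PARENT_IDS)]
    for tid, group in body.groupby("tetrad_id", sort=False):
        group = group.sort_values("spore_index")
        spores = tuple(tuple(row[list(markers)]) for _, row in group.iterrows())
        tetrads.append(
            TetradGenotypes(
                tetrad_id=str(tid),
                spores=spores,
                marker_order=markers,
                parental_haplotypes=(parents["parental_1"], parents["parental_2"]),
            )
        )
    return tetrads


def read_interval_config(path: str | Path) -> list[dict]:
    """YAML config listing marker intervals: `left`, `right`, optional `kb`."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    intervals = cfg.get("intervals")
    if not intervals:
        raise ValueError(f"{path}: config must define a non-empty 'intervals' list")
    for iv in intervals:
        if "left" not in iv or "right" not in iv:
            raise ValueError(f"{path}: each interval needs 'left' and 'right'")
    return intervals


def read_phase_config(path: str | Path) -> dict[str, dict[str, str]]:
    """YAML config mapping each marker to its parental alleles.

    ``phase: {marker: {P1: allele, P2: allele}}`` — unknown-phase input is
    rejected rather than inferred.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    phase = cfg.get("phase")
    if not phase:
        raise ValueError(f"{path}: config must define 'phase'")
    for marker, alleles in phase.items():
        if set(alleles) != {"P1", "P2"}:
            raise ValueError(f"{path}: phase for {marker!r} needs both P1 and P2")
    return phase


def read_spores(
    path: str | Path, phase: Mapping[str, Mapping[str, str]]
) -> list[SporeRecord]:
    """Read `spore_id  canavanine  marker...` rows, phased via config.

    Marker columns must all appear in the phase mapping; allele values are
    translated to parental-origin calls (spores with alleles matching
    neither parent keep the raw value and are excluded downstream).
    """
    df = _read_table(path, dtype=str)
    if df.columns[0] != "spore_id" or df.columns[1] != "canavanine":
        raise ValueError(f"{path}: first two columns must be spore_id, canavanine")
    markers = list(df.columns[2:])
    unphased = [m for m in markers if m not in phase]
    if unphased:
        raise ValueError(f"{path}: no phase configured for marker(s) {unphased}")
    lookup = {
        m: {phase[m]["P1"]: "P1", phase[m]["P2"]: "P2"} for m in markers
    }
    spores = []
    for row in df.itertuples():
        calls = tuple(
            lookup[m].get(getattr(row, m), str(getattr(row, m))) for m in markers
        )
        spores.append(
            SporeRecord(
                spore_id=str(row.spore_id),
                marker_calls=calls,
                canavanine=str(row.canavanine),
            )
        )
    return spores


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read `isolate_id  phase  position  ref  alt` rows."""
    df = _read_table(path, dtype=str)
    required = {"isolate_id", "phase", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        MutationRecord(
            isolate_id=str(row.isolate_id),
            position=int(row.position),
            ref="" if pd.isna(row.ref) or row.ref == "-" else str(row.ref),
            alt="" if pd.isna(row.alt) or row.alt == "-" else str(row.alt),
            phase_label=str(row.phase),
        )
        for row in df.itertuples()
    ]


def validate_refs(records: Sequence[MutationRecord], orf_fasta: str | Path) -> None:
    """Check each record's ref allele against the reporter ORF sequence."""
    from Bio import SeqIO

    seqs = list(SeqIO.parse(str(orf_fasta), "fasta"))
    if len(seqs) != 1:
        raise ValueError(f"{orf_fasta}: expected exactly one sequence")
    orf = str(seqs[0].seq).upper()
    for rec in records:
        expected = orf[rec.position - 1 : rec.position - 1 + len(rec.ref)]
        if rec.ref and expected != rec.ref:
            raise ValueError(
                f"isolate {rec.isolate_id}: ref {rec.ref!r} at {rec.position} "
                f"does not match ORF ({expected!r})"
            )


def write_tsv(df: pd.DataFrame, path: str | Path | None) -> None:
    """Write a table as TSV to a path, or to stdout when path is None."""
    import sys

    target = sys.stdout if path is None else path
    df.to_csv(target, sep="\t", index=False)
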