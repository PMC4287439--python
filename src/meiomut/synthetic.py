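"""Synthetic data generators for every analysis stage.

All generators are seeded through :class:`SimulationConfig` and are
deterministic for a fixed seed.  The models are deliberately minimal:
synchronous doubling growth for fluctuation cultures, a Poisson
no-chromatid-interference four-strand model for tetrads, per-interval
exchange probabilities with optional double-crossover thinning for
random spores, and a categorical class mixture for mutation lists.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .fluctuation import CultureObservation, FluctuationExperiment
from .spectrum import MutationRecord
from .spores import SporeRecord
from .tetrads import TetradGenotypes

__all__ = [
    "SimulationConfig",
    "simulate_fluctuation",
    "simulate_tetrads",
    "simulate_random_spores",
    "simulate_mutations",
]

logger = logging.getLogger(__name__)

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimulationConfig:
    """Parameters shared by the four generators.

    ``interval_cm`` maps interval names (in chromosome order) to genetic
    distances; markers are derived as the interval boundaries.
    ``co_association_enrichment`` multiplies per-interval exchange
    probabilities for spores that carry a reporter mutation (capped at 1).
    """

    seed: int = 0
    mutation_rate_per_division: float = 1e-7
    n_initial: int = 1_000
    n_final: int = 10_000_000
    n_cultures: int = 18
    interval_cm: dict[str, float] = field(
        default_factory=lambda: {"A": 5.0, "B": 5.0}
    )
    interference_strength: float = 0.0
    meiotic_mutation_prob: float = 0.1
    co_association_enrichment: float = 1.0
    spectrum_probs: dict[str, float] = field(
        default_factory=lambda: {
            "transition": 0.45,
            "transversion": 0.35,
            "contraction": 0.1,
            "expansion": 0.05,
            "complex": 0.05,
        }
    )
    orf_length: int = 1773
    #: "doubling": synchronous generations, mutant lineages double; cheap
    #: but quantizes clone sizes to powers of 2, which biases the MSS MLE
    #: downward by ~10% at m=10.  "continuous": Poisson mutations placed
    #: uniformly over cells born with clone size n_final/N — the growth
    #: model the MSS likelihood assumes; use it for parameter-recovery
    #: validation.
    growth_model: str = "doubling"

    def __post_init__(self) -> None:
        if self.growth_model not in ("doubling", "continuous"):
            raise ValueError(f"unknown growth_model: {self.growth_model!r}")
        if not 0.0 <= self.meiotic_mutation_prob <= 1.0:
            raise ValueError("meiotic_mutation_prob must be in [0, 1]")
        if self.co_association_enrichment < 1.0:
            raise ValueError("co_association_enrichment must be >= 1")
        if self.interference_strength < 0:
            raise ValueError("interference_strength must be >= 0")
        if any(cm < 0 for cm in self.interval_cm.values()):
            raise ValueError("interval cM must be >= 0")
        total = sum(self.spectrum_probs.values())
        if self.spectrum_probs and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"spectrum_probs must sum to 1, got {total}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_fluctuation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> FluctuationExperiment:
    """Simulate parallel cultures under synchronous-doubling growth.

    With ``growth_model="doubling"`` each culture doubles deterministically
    from ``n_initial`` to ``n_final``; at each generation, new mutations
    arise Poisson with mean rate x cells born, and every mutant lineage
    doubles thereafter.  With ``growth_model="continuous"`` the number of
    mutations per culture is Poisson(rate x cells born), each placed
    uniformly over the cells born, and a mutation arising when the
    population has size N leaves n_final / N descendants.  The returned
    mutant counts are whole-culture equivalents.
    """
    if config.n_final <= config.n_initial:
        raise ValueError("n_final must exceed n_initial")
    if config.mutation_rate_per_division < 0:
        raise ValueError("mutation rate must be >= 0")
    if config.mutation_rate_per_division > 0.1:
        warnings.warn(
            "per-division mutation rate > 0.1 per cell strains "
            "Luria-Delbruck assumptions",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = config.rng() if rng is None else rng
    generations = max(1, round(math.log2(config.n_final / config.n_initial)))
    final = config.n_initial * 2**generations
    rate = config.mutation_rate_per_division
    counts = np.zeros(config.n_cultures, dtype=np.int64)
    if config.growth_model == "doubling":
        for t in range(1, generations + 1):
            born = config.n_initial * 2 ** (t - 1)
            new = rng.poisson(rate * born, size=config.n_cultures)
            counts += new * 2 ** (generations - t)
    else:
        n_mutations = rng.poisson(rate * (final - config.n_initial), size=config.n_cultures)
        for c in range(config.n_cultures):
            if n_mutations[c]:
                sizes = rng.uniform(config.n_initial, final, size=n_mutations[c])
                counts[c] = int(np.floor(final / sizes).sum())
    counts = np.minimum(counts, final)
    cultures = [
        CultureObservation(culture_id=f"c{i:04d}", mutant_count=int(c), total_cells=final)
        for i, c in enumerate(counts)
    ]
    return FluctuationExperiment(cultures=cultures, label="simulated")


def _meiosis_chromatids(
    n_intervals: int,
    lam: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiosis under the four-strand no-chromatid-interference model.

    Returns a (4, n_markers) array of parental origins (0 or 1).
    Chromatids 0,1 start as parent 0 and 2,3 as parent 1; each crossover
    in interval ``i`` swaps all distal markers (> i) between one randomly
    chosen chromatid of each parent.
    """
    n_markers = n_intervals + 1
    chromatids = np.repeat(np.array([0, 0, 1, 1]), n_markers).reshape(4, n_markers)
    for i in range(n_intervals):
        for _ in range(rng.poisson(lam[i])):
            a = rng.integers(0, 2)
            b = 2 + rng.integers(0, 2)
            tail_a = chromatids[a, i + 1 :].copy()
            chromatids[a, i + 1 :] = chromatids[b, i + 1 :]
            chromatids[b, i + 1 :] = tail_a
    return chromatids


def _marker_names(config: SimulationConfig) -> list[str]:
    return [f"M{i}" for i in range(len(config.interval_cm) + 1)]


def simulate_tetrads(
    config: SimulationConfig,
    n_tetrads: int,
    rng: np.random.Generator | None = None,
) -> list[TetradGenotypes]:
    """Simulate full tetrads with Poisson crossovers per interval.

    Crossovers per bivalent in an interval of ``d`` cM are Poisson with
    mean ``d / 50`` (each crossover involves two of the four chromatids,
    so the expected per-chromatid exchange fraction is d/100).
    """
    rng = config.rng() if rng is None else rng
    cms = np.array(list(config.interval_cm.values()), dtype=float)
    if (cms > 50).any():
        warnings.warn(
            "interval > 50 cM: Perkins distance saturates", RuntimeWarning, stacklevel=2
        )
    lam = cms / 50.0
    markers = _marker_names(config)
    parent0 = tuple("P1" for _ in markers)
    parent1 = tuple("P2" for _ in markers)
    origin_to_call = np.array(["P1", "P2"])
    tetrads = []
    for t in range(n_tetrads):
        chromatids = _meiosis_chromatids(len(cms), lam, rng)
        spores = tuple(tuple(origin_to_call[row]) for row in chromatids)
        tetrads.append(
            TetradGenotypes(
                tetrad_id=f"t{t:05d}",
                spores=spores,
                marker_order=tuple(markers),
                parental_haplotypes=(parent0, parent1),
            )
        )
    return tetrads


def simulate_random_spores(
    config: SimulationConfig,
    n_spores: int,
    rng: np.random.Generator | None = None,
) -> list[SporeRecord]:
    """Simulate random spores with optional mutation-crossover association.

    Each spore is canavanine-resistant with probability
    ``meiotic_mutation_prob``; resistant spores have their per-interval
    exchange probabilities multiplied by ``co_association_enrichment``
    (capped at 1, with a log message when the cap binds).  Interference is
    implemented by thinning adjacent double exchanges: each adjacent pair
    of exchanged intervals is broken up (one side cleared at random) with
    probability ``1 - exp(-interference_strength)``.
    """
    rng = config.rng() if rng is None else rng
    base = np.array(list(config.interval_cm.values()), dtype=float) / 100.0
    enriched = base * config.co_association_enrichment
    if (enriched > 1.0).any():
        logger.info("enriched exchange probabilities capped at 1")
        enriched = np.minimum(enriched, 1.0)
    n_intervals = base.size
    markers = _marker_names(config)
    thin_prob = 1.0 - math.exp(-config.interference_strength)
    records = []
    is_mutant = rng.random(n_spores) < config.meiotic_mutation_prob
    for s in range(n_spores):
        probs = enriched if is_mutant[s] else base
        exchanged = rng.random(n_intervals) < probs
        if thin_prob > 0:
            for i in range(n_intervals - 1):
                if exchanged[i] and exchanged[i + 1] and rng.random() < thin_prob:
                    exchanged[i + rng.integers(0, 2)] = False
        calls = ["P1" if rng.random() < 0.5 else "P2"]
        for i in range(n_intervals):
            prev = calls[-1]
            if exchanged[i]:
                calls.append("P2" if prev == "P1" else "P1")
            else:
                calls.append(prev)
        records.append(
            SporeRecord(
                spore_id=f"s{s:06d}",
                marker_calls=tuple(calls),
                canavanine="resistant" if is_mutant[s] else "sensitive",
            )
        )
    return records


def _draw_mutation(
    klass: str, position: int, rng: np.random.Generator
) -> tuple[str, str]:
    """ref/alt alleles consistent with a mutation class."""
    base = "ACGT"[rng.integers(0, 4)]
    if klass == "transition":
        return base, TRANSITIONS[base]
    if klass == "transversion":
        choices = TRANSVERSIONS[base]
        return base, choices[rng.integers(0, len(choices))]
    if klass == "contraction":
        return base + base, base
    if klass == "expansion":
        return base, base + base
    raise ValueError(f"unknown mutation class: {klass}")


def simulate_mutations(
    config: SimulationConfig,
    n_isolates: int,
    phase_label: str = "meiosis",
    rng: np.random.Generator | None = None,
) -> list[MutationRecord]:
    """Simulate sequenced-mutation lists with a configurable spectrum.

    Positions are uniform over the ORF.  An isolate drawn as "complex"
    receives two distinct mutation records (so it classifies as complex
    at the isolate level); every other isolate receives one.
    """
    rng = config.rng() if rng is None else rng
    classes = list(config.spectrum_probs)
    probs = np.array([config.spectrum_probs[c] for c in classes])
    records: list[MutationRecord] = []
    draws = rng.choice(len(classes), size=n_isolates, p=probs)
    for i, ci in enumerate(draws):
        isolate = f"iso{i:05d}"
        klass = classes[ci]
        if klass == "complex":
            pos = sorted(rng.choice(config.orf_length, size=2, replace=False) + 1)
            for p in pos:
                sub = ("transition", "transversion")[rng.integers(0, 2)]
                ref, alt = _draw_mutation(sub, int(p), rng)
                records.append(
                    MutationRecord(isolate, int(p), ref, alt, phase_label)
                )
        else:
            pos = int(rng.integers(1, config.orf_length + 1))
            ref, alt = _draw_mutation(klass, pos, rng)
            records.append(MutationRecord(isolate, pos, ref, alt, phase_label))
    return records
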