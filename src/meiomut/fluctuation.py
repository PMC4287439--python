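"""Luria-Delbrück fluctuation analysis.

Estimates the expected number of mutation events per culture (``m``) from
parallel-culture mutant counts by the Ma-Sandri-Sarkar maximum-likelihood
method, converts it to a per-cell per-division mutation rate, and attaches
Foster-style 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CultureObservation",
    "FluctuationExperiment",
    "MutationRateEstimate",
    "mss_probabilities",
    "mss_log_likelihood",
    "mss_mle",
    "rate_from_m",
    "foster_ci95",
    "estimate_rate",
]

logger = logging.getLogger(__name__)

#: Counts above this value contribute a censored tail term to the
#: likelihood instead of an exact probability; the MSS recursion is
#: O(r^2) and jackpot cultures can carry counts in the millions.
DEFAULT_CENSOR_ABOVE = 1000


@dataclass(frozen=True)
class CultureObservation:
    """Mutant and total viable counts for one parallel culture.

    Counts are whole-culture equivalents: any dilution/plating scaling is
    the caller's responsibility (plating efficiency is assumed to be 1).
    """

    culture_id: str
    mutant_count: int
    total_cells: int

    def __post_init__(self) -> None:
        if self.total_cells <= 0:
            raise ValueError(f"total_cells must be positive, got {self.total_cells}")
        if self.mutant_count < 0:
            raise ValueError(f"mutant_count must be >= 0, got {self.mutant_count}")
        if self.mutant_count > self.total_cells:
            raise ValueError(
                f"mutant_count ({self.mutant_count}) exceeds total_cells "
                f"({self.total_cells}) for culture {self.culture_id!r}"
            )


@dataclass
class FluctuationExperiment:
    """An ordered collection of parallel cultures grown from small inocula."""

    cultures: list[CultureObservation]
    label: str = ""

    def __post_init__(self) -> None:
        self.cultures = list(self.cultures)

    @property
    def mutant_counts(self) -> np.ndarray:
        return np.array([c.mutant_count for c in self.cultures], dtype=np.int64)

    @property
    def total_cells(self) -> np.ndarray:
        return np.array([c.total_cells for c in self.cultures], dtype=np.float64)

    @property
    def mean_total_cells(self) -> float:
        return float(np.mean(self.total_cells))

    def __len__(self) -> int:
        return len(self.cultures)


@dataclass(frozen=True)
class MutationRateEstimate:
    """MSS-MLE point estimate with Foster 95% confidence interval."""

    m_hat: float
    rate: float
    ci95_low: float
    ci95_high: float
    n_cultures: int

    def __post_init__(self) -> None:
        if self.m_hat < 0:
            raise ValueError("m_hat must be >= 0")
        if not (self.ci95_low <= self.rate <= self.ci95_high):
            raise ValueError("confidence interval must bracket the rate")


def mss_probabilities(m: float, r_max: int) -> np.ndarray:
    """Mutant-count probabilities ``p_0 .. p_{r_max}`` under the MSS model.

    Uses the recursion ``p_0 = exp(-m)``,
    ``p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1)``.

    Parameters
    ----------
    m:
        Expected number of mutation events per culture (>= 0).
    r_max:
        Largest mutant count for which a probability is returned.

    Returns
    -------
    numpy.ndarray of shape ``(r_max + 1,)``.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if r_max < 0:
        raise ValueError(f"r_max must be >= 0, got {r_max}")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    if m == 0 or r_max == 0:
        return p
    # reciprocal[j] = 1 / j; the inner sum over i of p_i / (r - i + 1)
    # equals dot(p[r-1::-1], reciprocal[2:r+2]).
    reciprocal = np.zeros(r_max + 2, dtype=np.float64)
    reciprocal[1:] = 1.0 / np.arange(1, r_max + 2, dtype=np.float64)
    for r in range(1, r_max + 1):
        p[r] = (m / r) * np.dot(p[r - 1 :: -1], reciprocal[2 : r + 2])
    return p


def mss_log_likelihood(
    m: float,
    counts: Sequence[int] | np.ndarray,
    censor_above: int = DEFAULT_CENSOR_ABOVE,
) -> float:
    """Log-likelihood of observed mutant counts at a given ``m``.

    Counts larger than ``censor_above`` enter as a right-censored tail
    term ``log(1 - sum_{r<=censor_above} p_r)``, which keeps the O(r^2)
    recursion tractable in the presence of jackpot cultures.
    """
    counts = np.asarray(counts, dtype=np.int64)
    capped = np.minimum(counts, censor_above + 1)
    r_max = int(capped.max(initial=0))
    p = mss_probabilities(m, min(r_max, censor_above))
    tiny = 1e-300
    ll = 0.0
    censored = capped > censor_above
    if censored.any():
        tail = max(1.0 - p.sum(), tiny)
        ll += int(censored.sum()) * math.log(tail)
    exact = counts[~censored]
    ll += float(np.sum(np.log(np.maximum(p[exact], tiny))))
    return ll


def mss_mle(
    experiment: FluctuationExperiment | Sequence[int],
    censor_above: int = DEFAULT_CENSOR_ABOVE,
    tol: float = 1e-6,
) -> float:
    """Maximum-likelihood estimate of mutations per culture, ``m_hat``.

    Accepts a :class:`FluctuationExperiment` or a bare sequence of mutant
    counts.  All-zero counts return 0 (boundary maximum).  The search is a
    bounded derivative-free maximization on the log(m) scale and is
    deterministic for a given input and tolerance.
    """
    if isinstance(experiment, FluctuationExperiment):
        counts = experiment.mutant_counts
    else:
        counts = np.asarray(list(experiment), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("cannot estimate m from an empty experiment")
    if (counts < 0).any():
        raise ValueError("mutant counts must be >= 0")
    if not counts.any():
        return 0.0

    lo, hi = math.log(1e-6), math.log(float(counts.max()) + 10.0)

    def neg_ll(log_m: float) -> float:
        return -mss_log_likelihood(math.exp(log_m), counts, censor_above)

    res = minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    return float(math.exp(res.x))


def rate_from_m(
    m_hat: float, mean_total_cells: float, divisor: str = "final"
) -> float:
    """Convert ``m_hat`` to a per-cell per-division mutation rate.

    ``divisor="final"`` uses the mean final population N_t (rate = m/N_t);
    ``divisor="final-ln2"`` applies the ln(2) correction (rate = m/(N_t ln 2)).
    """
    if mean_total_cells <= 0:
        raise ValueError("mean_total_cells must be positive")
    if m_hat < 0:
        raise ValueError("m_hat must be >= 0")
    if divisor == "final":
        return m_hat / mean_total_cells
    if divisor == "final-ln2":
        return m_hat / (mean_total_cells * math.log(2))
    raise ValueError(f"unknown divisor convention: {divisor!r}")


def foster_ci95(m_hat: float, n_cultures: int) -> tuple[float, float]:
    """95% confidence interval for ``m_hat``, on the m scale.

    Symmetric on the ln(m) scale:
    ``sigma = 1.225 * m^-0.315 / sqrt(C)``, CI = ``exp(ln m +/- 1.96 sigma)``.

    ``m_hat == 0`` yields the degenerate interval ``(0, -ln(0.05)/C)``
    (the upper bound such that all-zero cultures remain plausible at the
    5% level), with a warning.
    """
    if n_cultures < 2:
        raise ValueError("need at least 2 cultures for a confidence interval")
    if m_hat < 0:
        raise ValueError("m_hat must be >= 0")
    if m_hat == 0:
        warnings.warn(
            "m_hat is 0; returning degenerate p0-method interval",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, -math.log(0.05) / n_cultures
    sigma = 1.225 * m_hat**-0.315 / math.sqrt(n_cultures)
    log_m = math.log(m_hat)
    return math.exp(log_m - 1.96 * sigma), math.exp(log_m + 1.96 * sigma)


def estimate_rate(
    experiment: FluctuationExperiment,
    divisor: str = "final",
    censor_above: int = DEFAULT_CENSOR_ABOVE,
) -> MutationRateEstimate:
    """Full pipeline: MSS-MLE, rate conversion, Foster 95% CI.

    Logs a warning when per-culture total populations are heterogeneous
    (CV > 0.5), since the rate conversion uses their arithmetic mean.
    """
    if len(experiment) < 2:
        raise ValueError("need at least 2 cultures")
    totals = experiment.total_cells
    cv = float(np.std(totals) / np.mean(totals))
    if cv > 0.5:
        logger.warning(
            "total_cells are heterogeneous across cultures (CV=%.2f); "
            "rate uses their arithmetic mean",
            cv,
        )
    m_hat = mss_mle(experiment, censor_above=censor_above)
    n_t = experiment.mean_total_cells
    rate = rate_from_m(m_hat, n_t, divisor=divisor)
    if m_hat > 0:
        m_lo, m_hi = foster_ci95(m_hat, len(experiment))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_lo, m_hi = foster_ci95(0.0, len(experiment))
    return MutationRateEstimate(
        m_hat=m_hat,
        rate=rate,
        ci95_low=rate_from_m(m_lo, n_t, divisor=divisor),
        ci95_high=rate_from_m(m_hi, n_t, divisor=divisor),
        n_cultures=len(experiment),
    )
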