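"""Shared chi-square helpers with small-expected-cell pooling."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["pooled_chi2_contingency"]


def pooled_chi2_contingency(
    table: np.ndarray,
    min_expected: float = 5.0,
) -> tuple[float, int, float]:
    """Pearson chi-square (no Yates correction) on a 2xK table.

    All-zero columns are dropped; then, while any expected cell falls
    below ``min_expected`` and more than two columns remain, the column
    with the smallest expected count is pooled into its neighbour.
    Returns (statistic, df, p).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square needs >= 2 nonzero columns and nonzero rows")

    def expected(t: np.ndarray) -> np.ndarray:
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    # pool the column with the smallest expected count into its neighbour
    # until every expected cell clears the threshold (or only 2 remain)
    while table.shape[1] > 2:
        exp = expected(table)
        if exp.min() >= min_expected:
            break
        col = int(np.argmin(exp.min(axis=0)))
        neighbour = col - 1 if col == table.shape[1] - 1 else col + 1
        table[:, neighbour] += table[:, col]
        table = np.delete(table, col, axis=1)

    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
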