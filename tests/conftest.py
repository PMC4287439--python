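from __future__ import annotations

import numpy as np
import pytest

from meiomut.fluctuation import mss_probabilities
from meiomut.tetrads import TetradGenotypes

# Published tetrad tallies used throughout the tests:
# (pd, npd, tt, printed_pct_recombination, printed_cm, cm_decimals, kb)
# pct is None where the printed cell is internally inconsistent with its
# own counts (garbled in typesetting) and excluded from assertions.
TETRAD_ROWS = [
    ("no-insert/natMX-MAT", 269, 0, 16, 5.6, 2.8, 1, 9.7),
    ("no-insert/MAT-kanMX", 140, 1, 144, 51.2, 26.3, 1, 22.5),
    ("coldspot-hemi/natMX-MAT", 243, 0, 8, 3.2, 1.6, 1, 9.7),
    ("coldspot-hemi/natMX-HIS3", 245, 0, 7, 2.8, 1.4, 1, 7.8),
    ("coldspot-hemi/HIS3-MAT", 252, 0, 3, 1.2, 0.59, 2, 1.85),
    ("coldspot-rev3/natMX-MAT", 199, 0, 9, 4.3, 2.16, 2, 9.7),
    ("coldspot-rev3/natMX-HIS3", 203, 0, 7, 3.3, 1.67, 2, 7.8),
    ("coldspot-rev3/HIS3-MAT", 211, 0, 1, 0.5, 0.24, 2, 1.85),
    ("coldspot-hom/natMX-MAT", 227, 0, 20, 8.1, 4.05, 2, 12.3),
    ("coldspot-hom/natMX-HIS3", 233, 0, 12, 4.9, 2.45, 2, 10.4),
    ("coldspot-hom/HIS3-MAT", 240, 0, 6, 2.4, 1.22, 2, 1.85),
    ("hotspot/natMX-MAT", 296, 0, 14, None, 2.26, 2, None),
    ("hotspot/MAT-HIS3", 246, 0, 61, 19.8, 9.93, 2, 11.0),
    ("hotspot/HIS3-kanMX", 224, 0, 79, 26.1, 13.0, 1, 14.5),
    ("hotspot/MAT-kanMX", 167, 2, 139, 46.4, 24.5, 1, 25.1),
]

# Published (meiotic, mitotic) rate pairs (x1e-8) and the fold printed
# next to them; the source rounds its inputs inconsistently, so folds
# recomputed from the printed pair can differ from print by up to 0.1.
FOLD_ROWS = [
    (37.0, 5.7, 6.5),
    (35.0, 6.1, 5.8),
    (7.0, 6.5, 1.1),
    (16.0, 2.0, 8.0),
    (49.0, 8.2, 5.9),
    (177.0, 8.4, 21.1),
]


def grid_search_mle(counts, step=1e-4, m_hi=None):
    """Independent brute-force MLE over the same log-likelihood.

    Dense grid on m; deliberately naive so it shares nothing with the
    bounded-search implementation beyond the probability recursion.
    """
    counts = np.asarray(counts, dtype=np.int64)
    r_max = int(counts.max())
    if m_hi is None:
        m_hi = max(5.0, float(counts.mean()) * 3)
    best_m, best_ll = 0.0, -np.inf
    for m in np.arange(step, m_hi + step, step):
        p = mss_probabilities(m, r_max)
        ll = float(np.log(np.maximum(p[counts], 1e-300)).sum())
        if ll > best_ll:
            best_ll, best_m = ll, float(m)
    return best_m


def make_tetrad(spores, parents=("AB", "ab"), tetrad_id="t0"):
    """Two-marker tetrad from compact strings like ("AB", "AB", "ab", "ab")."""
    return TetradGenotypes(
        tetrad_id=tetrad_id,
        spores=tuple(tuple(s) for s in spores),
        marker_order=("left", "right"),
        parental_haplotypes=tuple(tuple(p) for p in parents),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
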