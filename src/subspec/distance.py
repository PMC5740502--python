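"""Pairwise sample dissimilarity from allele-frequency profiles.

The dissimilarity between two samples is a normalized Manhattan distance
over pairwise-complete variant positions,

    d(S1, S2) = sum_i |S1_i - S2_i| / n,

where the sum runs over the n positions covered in both samples.  It is 0
for identical variation profiles and 1 for completely different ones.
Positions covered in only one sample are excluded, and a pair must share at
least ``min_positions`` (default 1000) positions for the distance to be
considered valid; otherwise it is missing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .formats import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "allele_distance",
    "distance_matrix",
    "complete_submatrix",
]

DEFAULT_MIN_POSITIONS = 1000


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarities with shared-position counts.

    ``d`` entries are in [0, 1] or NaN where fewer than ``min_positions``
    positions were pairwise complete; ``n_shared`` records those counts.
    """

    samples: list[str]
    d: np.ndarray
    n_shared: np.ndarray
    min_positions: int = DEFAULT_MIN_POSITIONS

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_shared = np.asarray(self.n_shared, dtype=int)
        n = len(self.samples)
        if self.d.shape != (n, n) or self.n_shared.shape != (n, n):
            raise ValueError("distance/count matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.d).any()

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = np.asarray([self.samples.index(s) for s in sample_ids], dtype=int)
        return DistanceMatrix(
            samples=list(sample_ids),
            d=self.d[np.ix_(idx, idx)],
            n_shared=self.n_shared[np.ix_(idx, idx)],
            min_positions=self.min_positions,
        )


def allele_distance(
    f1: np.ndarray, f2: np.ndarray, min_positions: int = DEFAULT_MIN_POSITIONS
) -> float:
    """Normalized Manhattan distance over pairwise-complete positions.

    Returns NaN when fewer than ``min_positions`` positions are non-missing
    in both vectors.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.size == 0 or f2.size == 0:
        raise ValueError("empty frequency vectors")
    if f1.shape != f2.shape:
        raise ValueError("frequency vectors not aligned")
    shared = ~np.isnan(f1) & ~np.isnan(f2)
    n = int(shared.sum())
    if n < min_positions:
        return float("nan")
    return float(np.abs(f1[shared] - f2[shared]).sum() / n)


def distance_matrix(
    ft: FrequencyTable, min_positions: int = DEFAULT_MIN_POSITIONS
) -> DistanceMatrix:
    """All pairwise :func:`allele_distance` values for a frequency table."""
    if ft.n_positions == 0 or ft.n_samples == 0:
        raise ValueError("empty frequency table")
    F = ft.freq
    mask = ~np.isnan(F)
    F0 = np.where(mask, F, 0.0)
    n = ft.n_samples
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    # column-at-a-time: O(n) vectorized passes over the positions axis
    for i in range(n - 1):
        diff = np.abs(F0[:, i : i + 1] - F0[:, i + 1 :])
        valid = mask[:, i : i + 1] & mask[:, i + 1 :]
        sums[i, i + 1 :] = np.where(valid, diff, 0.0).sum(axis=0)
        counts[i, i + 1 :] = valid.sum(axis=0)
    sums += sums.T
    counts += counts.T
    np.fill_diagonal(counts, mask.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    d[counts < min_positions] = np.nan
    np.fill_diagonal(d, np.where(counts.diagonal() >= min_positions, 0.0, np.nan))
    return DistanceMatrix(
        samples=list(ft.samples), d=d, n_shared=counts, min_positions=min_positions
    )


def complete_submatrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Remove samples until no off-diagonal entry is missing.

    Greedy: repeatedly drop the sample involved in the most missing pairs
    (ties broken by sample id order).  Partitioning around medoids needs a
    complete matrix; removals are logged.
    """
    keep = list(range(dm.n))
    removed: list[str] = []
    while True:
        sub = dm.d[np.ix_(keep, keep)]
        miss = np.isnan(sub)
        np.fill_diagonal(miss, False)
        if not miss.any():
            break
        counts = miss.sum(axis=1)
        worst = min(
            range(len(keep)), key=lambda t: (-counts[t], dm.samples[keep[t]])
        )
        removed.append(dm.samples[keep[worst]])
        del keep[worst]
        if len(keep) < 3:
            raise ValueError(
                "fewer than 3 samples with complete distances remain; "
                "consider lowering min_positions or coverage thresholds"
            )
    if removed:
        logger.info("removed %d samples with incomplete distances: %s",
                    len(removed), removed)
    return dm.submatrix([dm.samples[i] for i in keep])
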