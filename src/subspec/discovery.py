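"""Discovery-set selection: high-confidence samples, species and positions.

Accurate variant comparison requires samples in which the species genome is
both deep and broadly covered.  Per species, the discovery set keeps samples
with vertical coverage >= 5x and horizontal coverage >= 40% (inclusive
thresholds); only species with at least 50 such samples are delineated.
Variant positions are then restricted to those with >= 5x depth in at least
half of the discovery samples, so that only core-genome variation is
compared and missing values are not non-randomly distributed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .formats import CoverageSummary, FrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "DiscoveryConfig",
    "select_discovery_samples",
    "eligible_species",
    "filter_positions",
]


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds for discovery-set construction (all inclusive)."""

    min_vertical: float = 5.0
    min_horizontal: float = 0.40
    min_samples: int = 50
    min_position_depth: int = 5
    min_position_sample_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(
            self.min_vertical,
            self.min_horizontal,
            self.min_samples,
            self.min_position_depth,
            self.min_position_sample_fraction,
        ) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_horizontal > 1 or self.min_position_sample_fraction > 1:
            raise ValueError("fractional thresholds must be <= 1")


def select_discovery_samples(
    cov: CoverageSummary, species_id: str, cfg: DiscoveryConfig = DiscoveryConfig()
) -> list[str]:
    """Samples with vertical >= min_vertical and horizontal >= min_horizontal.

    Order follows the coverage table (stable).  An absent species yields an
    empty list with a warning.
    """
    sub = cov.for_species(species_id)
    if sub.empty:
        logger.warning("species %s absent from coverage summary", species_id)
        return []
    keep = (sub["vertical"] >= cfg.min_vertical) & (
        sub["horizontal"] >= cfg.min_horizontal
    )
    return list(sub.loc[keep, "sample_id"])


def eligible_species(
    cov: CoverageSummary, cfg: DiscoveryConfig = DiscoveryConfig()
) -> list[str]:
    """Species whose discovery-sample count reaches ``cfg.min_samples``."""
    out = []
    for sp in cov.species_ids():
        n = len(select_discovery_samples(cov, sp, cfg))
        if n >= cfg.min_samples:
            out.append(sp)
    return out


def filter_positions(
    ft: FrequencyTable,
    discovery_samples: list[str],
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> FrequencyTable:
    """Restrict to discovery samples and well-covered positions.

    A position is kept when its depth is >= ``cfg.min_position_depth`` in at
    least ``ceil(min_position_sample_fraction * n_discovery)`` discovery
    samples ("at least half", ceiling on odd counts).  Without a depth
    matrix the input is assumed pre-filtered and positions pass unchanged.
    """
    unknown = [s for s in discovery_samples if s not in ft.samples]
    if unknown:
        raise ValueError(f"discovery samples absent from frequency table: {unknown}")
    sub = ft.subset(sample_ids=discovery_samples)
    if sub.depth is None:
        logger.warning(
            "frequency table has no depth matrix; position filter skipped"
        )
        return sub
    need = math.ceil(cfg.min_position_sample_fraction * len(discovery_samples))
    counts = (sub.depth >= cfg.min_position_depth).sum(axis=1)
    keep = np.flatnonzero(counts >= need)
    return sub.subset(position_idx=keep)
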