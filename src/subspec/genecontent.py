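"""Reference-genome-free inference of species and subspecies gene content.

Genes are binned by co-abundance: a gene whose relative-abundance profile
across samples tracks the abundance of a species belongs to that species'
core (SC), while a gene tracking one subspecies' abundance belongs to that
subspecies-specific core (SSSC).  A gene is assigned when its Pearson
correlation on log10-transformed relative abundances exceeds 0.8 and its
Spearman correlation exceeds 0.6 for at least one target, and it is
attributed to the passing target it correlates highest with (best hit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats import AbundanceTable

logger = logging.getLogger(__name__)

__all__ = ["GeneAssignment", "correlate_genes", "partition_cores"]

MIN_PEARSON = 0.8
MIN_SPEARMAN = 0.6
MIN_SHARED_SAMPLES = 10


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    assigned_taxon: str | None  # species id (SC), subspecies label (SSSC), or None
    pearson_r: float
    spearman_rho: float
    n_samples: int
    reason: str = ""


def _pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero abundance, for log10 of zeros."""
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return 1e-12
    return float(nonzero.min() / 2.0)


def correlate_genes(
    genes: AbundanceTable,
    targets: AbundanceTable,
    min_pearson: float = MIN_PEARSON,
    min_spearman: float = MIN_SPEARMAN,
    min_shared_samples: int = MIN_SHARED_SAMPLES,
    pseudocount: float | None = None,
) -> list[GeneAssignment]:
    """Assign genes to the species/subspecies they co-vary with.

    ``targets`` holds the species abundance row plus one row per
    subspecies.  Per gene and target, Pearson is computed on
    log10(abundance + pseudocount) and Spearman on the raw values, over
    samples where the target is detected (> 0) and gene and target are not
    both zero.  The gene is assigned to the passing target with the highest
    Pearson r (ties by Spearman, then lexicographic target id).
    """
    shared = [s for s in genes.samples if s in set(targets.samples)]
    if len(shared) < min_shared_samples:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= {min_shared_samples}"
        )
    g = genes.table[shared].to_numpy(dtype=float)
    t = targets.table[shared].to_numpy(dtype=float)
    pc_g = _pseudocount(g) if pseudocount is None else pseudocount
    pc_t = _pseudocount(t) if pseudocount is None else pseudocount
    target_ids = targets.taxa
    out: list[GeneAssignment] = []
    for gi, gene_id in enumerate(genes.taxa):
        passing: list[tuple[float, float, str, int]] = []
        degenerate = False
        for ti, taxon in enumerate(target_ids):
            use = (t[ti] > 0) & ~((g[gi] == 0) & (t[ti] == 0))
            n = int(use.sum())
            if n < min_shared_samples:
                continue
            gv = g[gi, use]
            tv = t[ti, use]
            if np.ptp(gv) == 0 or np.ptp(tv) == 0:
                degenerate = True
                continue
            r = float(sps.pearsonr(np.log10(gv + pc_g), np.log10(tv + pc_t))[0])
            rho = float(sps.spearmanr(gv, tv)[0])
            if np.isnan(r) or np.isnan(rho):
                degenerate = True
                continue
            if r > min_pearson and rho > min_spearman:
                passing.append((r, rho, taxon, n))
        if passing:
            r, rho, taxon, n = min(passing, key=lambda c: (-c[0], -c[1], c[2]))
            out.append(GeneAssignment(gene_id, taxon, r, rho, n))
        else:
            out.append(
                GeneAssignment(
                    gene_id, None, np.nan, np.nan, len(shared),
                    reason="degenerate profile" if degenerate else
                    "no target passed correlation thresholds",
                )
            )
    n_assigned = sum(a.assigned_taxon is not None for a in out)
    logger.info("assigned %d/%d genes", n_assigned, len(out))
    return out


def partition_cores(assignments: list[GeneAssignment]) -> dict[str, set[str]]:
    """Split assigned genes into SC and per-subspecies SSSC sets.

    Keys are the assigned taxon ids (species id for SC, MGSS label for
    SSSC); sets are disjoint by construction because each gene has at most
    one best hit.  Unassigned genes are omitted.
    """
    cores: dict[str, set[str]] = {}
    for a in assignments:
        if a.assigned_taxon is None:
            continue
        cores.setdefault(a.assigned_taxon, set()).add(a.gene_id)
    sizes = {k: len(v) for k, v in sorted(cores.items())}
    logger.info("core sizes: %s", sizes)
    return cores
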