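"""Subspecies delineation: PAM clustering with prediction-strength model choice.

Samples are partitioned with partitioning around medoids (PAM, BUILD +
SWAP) for every candidate number of clusters k in [2, k_max] (default
k_max = 10), keeping one time point per individual.  The support of each k
is measured by the prediction strength of Tibshirani & Walther: samples are
split in half, both halves are clustered, test samples are classified to
the nearest training medoid, and the split's score is the worst-case (over
test clusters) fraction of within-cluster pairs that the training
classification keeps together.  The chosen number of subspecies is the
highest k whose mean prediction strength exceeds 0.8; when no k qualifies
the species is reported as having no detectable substructure (k = 1).

Resulting clusters are named MGSS1..MGSSk (metagenomic subspecies), ordered
by decreasing size so repeated runs are comparable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .distance import DistanceMatrix, complete_submatrix, distance_matrix
from .formats import CoverageSummary, FrequencyTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "DelineationConfig",
    "SubspeciesModel",
    "deduplicate_subjects",
    "pam",
    "prediction_strength",
    "choose_k",
    "delineate",
    "subspecies_label",
]

_SWAP_TOL = 1e-12
_MAX_SWAP_ITER = 500


def _n_medoid_sets(n: int, k: int) -> int:
    try:
        return math.comb(n, k)
    except OverflowError:  # pragma: no cover
        return 10**18


def subspecies_label(i: int) -> str:
    """Canonical subspecies name for 1-based cluster index ``i``."""
    return f"MGSS{i}"


@dataclass(frozen=True)
class DelineationConfig:
    """Tunables for subspecies delineation."""

    min_positions: int = 1000
    k_max: int = 10
    ps_threshold: float = 0.8
    n_splits: int = 25
    min_samples: int = 50
    dedup_rule: str = "first"
    seed: int = 0


@dataclass
class SubspeciesModel:
    """Fitted per-species subspecies structure.

    ``assignments`` maps retained discovery samples to MGSS labels;
    ``medoids`` maps each label to its medoid sample.  ``ps_curve`` records
    the mean prediction strength per candidate k.  ``genotyping_positions``
    is attached by :mod:`subspec.genotype` after fitting.
    """

    species_id: str
    k: int
    assignments: dict[str, str]
    medoids: dict[str, str]
    ps_curve: dict[int, float]
    seed: int
    removed_samples: list[str] = field(default_factory=list)
    genotyping_positions: Any = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        labels = {subspecies_label(i) for i in range(1, self.k + 1)}
        extra = set(self.assignments.values()) - labels
        if extra:
            raise ValueError(f"assignment labels outside MGSS1..MGSS{self.k}: {extra}")
        for lab, med in self.medoids.items():
            if self.assignments.get(med) != lab:
                raise ValueError(f"medoid {med} not assigned to its cluster {lab}")

    @property
    def labels(self) -> list[str]:
        return [subspecies_label(i) for i in range(1, self.k + 1)]

    def to_dict(self) -> dict:
        gps = self.genotyping_positions
        return {
            "species_id": self.species_id,
            "k": self.k,
            "assignments": dict(self.assignments),
            "medoids": dict(self.medoids),
            "ps_curve": {str(kk): float(v) for kk, v in self.ps_curve.items()},
            "seed": int(self.seed),
            "removed_samples": list(self.removed_samples),
            "genotyping_positions": None if gps is None else gps.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubspeciesModel":
        from .genotype import GenotypingPositionSet

        gps = d.get("genotyping_positions")
        return cls(
            species_id=d["species_id"],
            k=int(d["k"]),
            assignments=dict(d["assignments"]),
            medoids=dict(d["medoids"]),
            ps_curve={int(kk): float(v) for kk, v in d["ps_curve"].items()},
            seed=int(d["seed"]),
            removed_samples=list(d.get("removed_samples", [])),
            genotyping_positions=None if gps is None else GenotypingPositionSet.from_dict(gps),
        )


# ---------------------------------------------------------------------------
# subject deduplication


def deduplicate_subjects(
    samples: list[str],
    meta: SampleMetadata,
    rule: str = "first",
    cov: CoverageSummary | None = None,
    species_id: str | None = None,
) -> list[str]:
    """Keep one sample per subject.

    ``rule='first'`` keeps the earliest collection day (ties by sample id);
    ``rule='deepest'`` keeps the sample with highest vertical coverage for
    ``species_id`` (requires ``cov``).  Output preserves input order.
    """
    if rule not in ("first", "deepest"):
        raise ValueError(f"unknown deduplication rule {rule!r}")
    known = set(meta.samples)
    missing = [s for s in samples if s not in known]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    sub = meta.table.set_index("sample_id")
    if rule == "deepest":
        if cov is None or species_id is None:
            raise ValueError("rule='deepest' requires a coverage summary and species")
        csub = cov.for_species(species_id).set_index("sample_id")["vertical"]
        key = lambda s: (-float(csub.get(s, -np.inf)), s)
    else:
        key = lambda s: (float(sub.at[s, "collection_day"]), s)
    best: dict[str, str] = {}
    for s in samples:
        subj = sub.at[s, "subject_id"]
        if subj not in best or key(s) < key(best[subj]):
            best[subj] = s
    chosen = set(best.values())
    return [s for s in samples if s in chosen]


# ---------------------------------------------------------------------------
# PAM


_EXHAUSTIVE_LIMIT = 2000  # medoid sets; tiny instances are solved exactly


def _pam_core(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-cost medoids on a complete distance matrix.

    Tiny instances (at most ``_EXHAUSTIVE_LIMIT`` candidate medoid sets)
    are solved exactly by enumeration; larger ones by BUILD followed by
    steepest-descent SWAP, the classical PAM local search.  Returns
    (medoid indices in slot order, labels as slot indices).
    Deterministic: ties are broken by lowest index.
    """
    n = d.shape[0]
    if _n_medoid_sets(n, k) <= _EXHAUSTIVE_LIMIT:
        best, best_obj = None, np.inf
        for cand in itertools.combinations(range(n), k):
            obj = d[list(cand)].min(axis=0).sum()
            if obj < best_obj - _SWAP_TOL:
                best, best_obj = cand, obj
        med = np.asarray(best, dtype=int)
        labels = np.argmin(d[med], axis=0)
        labels[med] = np.arange(k)
        return med, labels
    # BUILD: first medoid minimizes total distance, then greedy max-gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    d1 = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d1[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        d1 = np.minimum(d1, d[j])
    # SWAP: best-improvement until local optimum
    med = np.asarray(medoids, dtype=int)
    for _ in range(_MAX_SWAP_ITER):
        dm = d[med]  # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        a1 = order[0]  # nearest medoid slot per point
        pts = np.arange(n)
        d1 = dm[a1, pts]
        d2 = dm[order[1], pts] if k > 1 else np.full(n, np.inf)
        is_med = np.zeros(n, dtype=bool)
        is_med[med] = True
        cand = np.flatnonzero(~is_med)
        best_delta = -_SWAP_TOL
        best_pair: tuple[int, int] | None = None
        for j in cand:
            dj = d[j]
            gain = np.minimum(dj - d1, 0.0)
            w = (np.minimum(dj, d2) - d1) - gain
            deltas = gain.sum() + np.bincount(a1, weights=w, minlength=k)
            i = int(np.argmin(deltas))
            if deltas[i] < best_delta:
                best_delta = float(deltas[i])
                best_pair = (i, int(j))
        if best_pair is None:
            break
        med[best_pair[0]] = best_pair[1]
    labels = np.argmin(d[med], axis=0)
    labels[med] = np.arange(k)  # a medoid always belongs to its own cluster
    return med, labels


def pam(dm: DistanceMatrix | np.ndarray, k: int) -> tuple[list[int], np.ndarray]:
    """Partitioning around medoids for ``k`` clusters.

    Accepts a :class:`DistanceMatrix` (must be complete) or a square array.
    Returns medoid indices (slot order) and per-sample slot labels.
    """
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    if isinstance(dm, DistanceMatrix) and not dm.is_complete:
        raise ValueError("distance matrix has missing entries; complete it first")
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    med, labels = _pam_core(d, k)
    return [int(m) for m in med], labels


def pam_objective(d: np.ndarray, medoids: list[int]) -> float:
    """Total distance of every point to its nearest medoid."""
    return float(d[np.asarray(medoids, dtype=int)].min(axis=0).sum())


# ---------------------------------------------------------------------------
# prediction strength


def _split_score(
    d: np.ndarray, train: np.ndarray, test: np.ndarray, k: int
) -> float:
    """Prediction strength of one train/test split."""
    med_tr, _ = _pam_core(d[np.ix_(train, train)], k)
    _, lab_te = _pam_core(d[np.ix_(test, test)], k)
    # classify test samples to the nearest training medoid
    cls = np.argmin(d[np.ix_(test, train[med_tr])], axis=1)
    worst = 1.0
    for c in range(k):
        members = np.flatnonzero(lab_te == c)
        m = members.size
        if m < 2:
            continue  # singleton clusters have no pairs and contribute 1
        counts = np.bincount(cls[members], minlength=k)
        co = (counts * (counts - 1)).sum() / (m * (m - 1))
        worst = min(worst, float(co))
    return worst


def prediction_strength(
    dm: DistanceMatrix | np.ndarray,
    k: int,
    n_splits: int = 25,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Mean prediction strength of k clusters over repeated half-splits.

    For each of ``n_splits`` random 50/50 splits both halves are clustered
    with PAM; test samples are classified to the nearest training medoid and
    the split scores the minimum, over test clusters, of the fraction of
    within-cluster pairs co-assigned by that classification.  ``k=1``
    returns 1 by definition.
    """
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    if isinstance(dm, DistanceMatrix) and not dm.is_complete:
        raise ValueError("distance matrix has missing entries; complete it first")
    n = d.shape[0]
    if k == 1:
        return 1.0
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2*k} samples for k={k}, have {n}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scores = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        test = np.sort(perm[:half])
        train = np.sort(perm[half:])
        scores.append(_split_score(d, train, test, k))
    return float(np.mean(scores))


def choose_k(
    ps_curve: Mapping[int, float], threshold: float = 0.8, k_max: int = 10
) -> int:
    """Highest k with prediction strength strictly above ``threshold``.

    When no candidate qualifies there is insufficient evidence for distinct
    subspecies and 1 is returned.
    """
    good = [kk for kk, ps in ps_curve.items() if kk <= k_max and ps > threshold]
    return max(good) if good else 1


# ---------------------------------------------------------------------------
# end-to-end delineation


def delineate(
    ft: FrequencyTable,
    meta: SampleMetadata,
    cfg: DelineationConfig = DelineationConfig(),
    cov: CoverageSummary | None = None,
) -> SubspeciesModel:
    """Delineate subspecies for the (single) species in ``ft``.

    Composes subject deduplication, distance computation, completion of the
    distance matrix, the prediction-strength curve over k = 2..k_max, and a
    final PAM fit at the chosen k.  Labels are MGSS1..MGSSk ordered by
    decreasing cluster size (ties by medoid sample id).
    """
    species = ft.species_ids()
    if len(species) != 1:
        raise ValueError(f"expected one species in table, found {species}")
    species_id = species[0]
    samples = deduplicate_subjects(
        ft.samples, meta, rule=cfg.dedup_rule, cov=cov, species_id=species_id
    )
    if len(samples) < cfg.min_samples:
        raise ValueError(
            f"{species_id}: only {len(samples)} samples after deduplication "
            f"(minimum {cfg.min_samples})"
        )
    sub = ft.subset(sample_ids=samples)
    dm = distance_matrix(sub, min_positions=cfg.min_positions)
    dm_c = complete_submatrix(dm)
    removed = [s for s in samples if s not in dm_c.samples]
    n = dm_c.n
    ps_curve: dict[int, float] = {}
    for kk in range(2, cfg.k_max + 1):
        if n // 2 < kk:
            break
        # independent seed stream per k: curve entries do not depend on k_max
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, kk)))
        ps_curve[kk] = prediction_strength(dm_c, kk, n_splits=cfg.n_splits, seed=rng)
    k = choose_k(ps_curve, threshold=cfg.ps_threshold, k_max=cfg.k_max)
    if k == 1:
        center = int(np.argmin(dm_c.d.sum(axis=1)))
        assignments = {s: subspecies_label(1) for s in dm_c.samples}
        medoids = {subspecies_label(1): dm_c.samples[center]}
    else:
        med, labels = pam(dm_c, k)
        sizes = np.bincount(labels, minlength=k)
        order = sorted(
            range(k), key=lambda c: (-int(sizes[c]), dm_c.samples[med[c]])
        )
        rank = {c: r for r, c in enumerate(order)}
        assignments = {
            s: subspecies_label(rank[int(c)] + 1) for s, c in zip(dm_c.samples, labels)
        }
        medoids = {
            subspecies_label(rank[c] + 1): dm_c.samples[med[c]] for c in range(k)
        }
    logger.info(
        "%s: k=%d over %d samples (PS curve %s)", species_id, k, n,
        {kk: round(v, 3) for kk, v in ps_curve.items()},
    )
    return SubspeciesModel(
        species_id=species_id,
        k=k,
        assignments=assignments,
        medoids=medoids,
        ps_curve=ps_curve,
        seed=cfg.seed,
        removed_samples=removed,
    )
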