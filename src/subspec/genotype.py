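"""Genotyping positions: subspecies assignment and quantification.

A genotyping position for subspecies s is a variant position whose mean
non-reference allele frequency among samples assigned to s exceeds the
pooled mean among all other assigned samples by more than a threshold
(default 0.8).  Such positions carry the allele at high frequency in one
subspecies and not any of the others, and allow subspecies to be assigned
and quantified in arbitrary samples — including low-coverage samples
outside the discovery set.

A sample's frequency for subspecies s is the median allele frequency over
s's covered genotyping positions.  When the per-subspecies frequencies sum
to below 0.8 or above 1.2 no subspecies is assigned for that sample.
Subspecies abundance is the species relative abundance multiplied by the
subspecies frequency; a subspecies holding more than 90% of the summed
frequency is called dominant, and exclusive when it holds all of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster import SubspeciesModel
from .formats import FrequencyTable, PositionKey

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypingPosition",
    "GenotypingPositionSet",
    "ProfileEntry",
    "SubspeciesProfile",
    "genotyping_positions",
    "quantify",
    "subspecies_abundance",
    "dominance_call",
    "assign_cohort",
]

DELTA_THRESHOLD = 0.8
SUM_LOW = 0.8
SUM_HIGH = 1.2
DOMINANCE_THRESHOLD = 0.9
EXCLUSIVITY_TOL = 1e-9


@dataclass(frozen=True)
class GenotypingPosition:
    position: PositionKey
    mean_in: float
    mean_out: float

    @property
    def delta(self) -> float:
        return self.mean_in - self.mean_out


@dataclass
class GenotypingPositionSet:
    """Discriminating positions per subspecies label."""

    species_id: str
    by_label: dict[str, list[GenotypingPosition]]
    delta_threshold: float = DELTA_THRESHOLD

    @property
    def labels(self) -> list[str]:
        return list(self.by_label)

    def counts(self) -> dict[str, int]:
        return {lab: len(v) for lab, v in self.by_label.items()}

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "delta_threshold": self.delta_threshold,
            "by_label": {
                lab: [
                    {
                        "position": str(gp.position),
                        "mean_in": gp.mean_in,
                        "mean_out": gp.mean_out,
                    }
                    for gp in gps
                ]
                for lab, gps in self.by_label.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenotypingPositionSet":
        return cls(
            species_id=d["species_id"],
            delta_threshold=float(d["delta_threshold"]),
            by_label={
                lab: [
                    GenotypingPosition(
                        position=PositionKey.parse(g["position"]),
                        mean_in=float(g["mean_in"]),
                        mean_out=float(g["mean_out"]),
                    )
                    for g in gps
                ]
                for lab, gps in d["by_label"].items()
            },
        )


@dataclass
class ProfileEntry:
    """Subspecies quantification for one sample."""

    sample_id: str
    frequencies: dict[str, float]  # median allele frequency per subspecies
    status: str  # "assigned" | "unassigned"
    reason: str = ""
    dominant: str | None = None
    exclusive: bool = False
    abundances: dict[str, float] | None = None

    @property
    def shares(self) -> dict[str, float]:
        """Frequencies renormalized to sum to 1 (defined when assigned)."""
        total = sum(self.frequencies.values())
        if total <= 0:
            return {lab: np.nan for lab in self.frequencies}
        return {lab: f / total for lab, f in self.frequencies.items()}


@dataclass
class SubspeciesProfile:
    """Per-sample subspecies quantifications for one species."""

    species_id: str
    entries: list[ProfileEntry]

    def entry(self, sample_id: str) -> ProfileEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for lab, f in e.frequencies.items():
                rows.append(
                    {
                        "sample_id": e.sample_id,
                        "species_id": self.species_id,
                        "subspecies": lab,
                        "frequency": f,
                        "abundance": (
                            np.nan if e.abundances is None else e.abundances.get(lab)
                        ),
                        "status": e.status,
                        "dominant": e.dominant == lab,
                        "exclusive": e.exclusive and e.dominant == lab,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def genotyping_positions(
    ft: FrequencyTable,
    model: SubspeciesModel,
    delta_threshold: float = DELTA_THRESHOLD,
) -> GenotypingPositionSet:
    """Select positions discriminating each subspecies from the rest.

    For each subspecies and position, the in-group mean frequency (over
    samples assigned to it, missing excluded) is compared with the pooled
    mean over all other assigned samples; the position genotypes the
    subspecies when mean_in - mean_out strictly exceeds ``delta_threshold``.
    """
    if model.k < 2:
        raise ValueError("genotyping positions require a model with k >= 2")
    assigned = [s for s in ft.samples if s in model.assignments]
    if not assigned:
        raise ValueError("no assigned samples present in frequency table")
    sub = ft.subset(sample_ids=assigned)
    labels = np.asarray([model.assignments[s] for s in assigned])
    by_label: dict[str, list[GenotypingPosition]] = {}
    F = sub.freq
    valid = ~np.isnan(F)
    for lab in model.labels:
        in_mask = labels == lab
        with np.errstate(invalid="ignore", divide="ignore"):
            n_in = (valid & in_mask).sum(axis=1)
            n_out = (valid & ~in_mask).sum(axis=1)
            mean_in = np.where(in_mask, np.nan_to_num(F), 0.0).sum(axis=1) / np.maximum(
                n_in, 1
            )
            mean_out = np.where(~in_mask, np.nan_to_num(F), 0.0).sum(
                axis=1
            ) / np.maximum(n_out, 1)
        ok = (n_in > 0) & (n_out > 0) & (mean_in - mean_out > delta_threshold)
        by_label[lab] = [
            GenotypingPosition(
                position=sub.positions[i],
                mean_in=float(mean_in[i]),
                mean_out=float(mean_out[i]),
            )
            for i in np.flatnonzero(ok)
        ]
        if not by_label[lab]:
            logger.warning(
                "%s/%s: no genotyping positions found", model.species_id, lab
            )
    return GenotypingPositionSet(
        species_id=model.species_id,
        by_label=by_label,
        delta_threshold=delta_threshold,
    )


def quantify(
    freqs: Mapping[PositionKey, float],
    gps: GenotypingPositionSet,
    sum_low: float = SUM_LOW,
    sum_high: float = SUM_HIGH,
) -> ProfileEntry:
    """Quantify subspecies in one sample from its allele frequencies.

    ``freqs`` maps positions to frequencies (NaN or absent = not covered).
    The frequency of each subspecies is the median over its covered
    genotyping positions; the sample is unassigned when those frequencies
    sum to below ``sum_low`` or above ``sum_high`` or when no genotyping
    position of any subspecies is covered.
    """
    frequencies: dict[str, float] = {}
    any_covered = False
    for lab, positions in gps.by_label.items():
        vals = [
            freqs[g.position]
            for g in positions
            if g.position in freqs and not np.isnan(freqs[g.position])
        ]
        if vals:
            any_covered = True
            frequencies[lab] = float(np.median(vals))
        else:
            frequencies[lab] = np.nan
    if not any_covered:
        return ProfileEntry(
            sample_id="", frequencies=frequencies, status="unassigned",
            reason="no coverage",
        )
    if any(np.isnan(f) for f in frequencies.values()):
        return ProfileEntry(
            sample_id="", frequencies=frequencies, status="unassigned",
            reason="subspecies without covered genotyping positions",
        )
    total = sum(frequencies.values())
    if total < sum_low or total > sum_high:
        return ProfileEntry(
            sample_id="", frequencies=frequencies, status="unassigned",
            reason=f"frequency sum {total:.3f} outside [{sum_low}, {sum_high}]",
        )
    return ProfileEntry(sample_id="", frequencies=frequencies, status="assigned")


def subspecies_abundance(
    entry: ProfileEntry, species_abundance: float
) -> dict[str, float] | None:
    """Species relative abundance split by subspecies frequency."""
    if species_abundance < 0:
        raise ValueError("species abundance must be >= 0")
    if entry.status != "assigned":
        return None
    return {lab: species_abundance * f for lab, f in entry.frequencies.items()}


def dominance_call(
    entry: ProfileEntry, dominance_threshold: float = DOMINANCE_THRESHOLD
) -> tuple[str | None, bool]:
    """Dominant subspecies (share of summed frequencies > threshold), if any.

    A dominant subspecies is exclusive when its share is 1 (within 1e-9).
    """
    if entry.status != "assigned":
        raise ValueError("dominance is defined only for assigned profiles")
    shares = entry.shares
    dominant = None
    exclusive = False
    for lab, share in shares.items():
        if share > dominance_threshold:
            dominant = lab
            exclusive = share >= 1.0 - EXCLUSIVITY_TOL
            break
    return dominant, exclusive


def assign_cohort(
    ft_new: FrequencyTable,
    gps: GenotypingPositionSet,
    species_abundances: Mapping[str, float] | None = None,
    sum_low: float = SUM_LOW,
    sum_high: float = SUM_HIGH,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> SubspeciesProfile:
    """Quantify subspecies in every sample of a (possibly new) cohort.

    ``species_abundances`` maps sample ids to the species' relative
    abundance; when given, per-subspecies abundances are attached.
    """
    wanted = {g.position for gps_l in gps.by_label.values() for g in gps_l}
    pos_index = {p: i for i, p in enumerate(ft_new.positions) if p in wanted}
    if not pos_index:
        raise ValueError(
            f"no overlap between cohort positions and genotyping positions "
            f"of {gps.species_id}"
        )
    entries = []
    for j, sample in enumerate(ft_new.samples):
        freqs = {p: ft_new.freq[i, j] for p, i in pos_index.items()}
        entry = quantify(freqs, gps, sum_low=sum_low, sum_high=sum_high)
        entry.sample_id = sample
        if entry.status == "assigned":
            entry.dominant, entry.exclusive = dominance_call(
                entry, dominance_threshold
            )
            if species_abundances is not None and sample in species_abundances:
                entry.abundances = subspecies_abundance(
                    entry, float(species_abundances[sample])
                )
        entries.append(entry)
    n_assigned = sum(e.status == "assigned" for e in entries)
    logger.info(
        "%s: %d/%d samples assigned", gps.species_id, n_assigned, len(entries)
    )
    return SubspeciesProfile(species_id=gps.species_id, entries=entries)
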