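"""End-to-end orchestration: discover -> delineate -> genotype -> profile.

Per eligible species the pipeline applies the discovery filters, computes
distances, delineates subspecies, extracts genotyping positions and writes
the fitted model; profiling then quantifies subspecies in a (possibly new)
cohort.  A run manifest records every effective parameter, the seed and
input fingerprints, so identical inputs, configuration and seed produce
identical output directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .cluster import DelineationConfig, SubspeciesModel, delineate
from .discovery import DiscoveryConfig, eligible_species, filter_positions, select_discovery_samples
from .formats import (
    AbundanceTable,
    CoverageSummary,
    FrequencyTable,
    SampleMetadata,
    write_model,
)
from .genotype import (
    DELTA_THRESHOLD,
    DOMINANCE_THRESHOLD,
    SUM_HIGH,
    SUM_LOW,
    SubspeciesProfile,
    assign_cohort,
    genotyping_positions,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_delineation", "run_profile"]


@dataclass(frozen=True)
class RunConfig:
    """All effective parameters of a pipeline run."""

    discovery: DiscoveryConfig = DiscoveryConfig()
    delineation: DelineationConfig = DelineationConfig()
    delta_threshold: float = DELTA_THRESHOLD
    sum_low: float = SUM_LOW
    sum_high: float = SUM_HIGH
    dominance_threshold: float = DOMINANCE_THRESHOLD
    seed: int = 0
    species: tuple[str, ...] | None = None  # None = all eligible

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = None if self.species is None else list(self.species)
        return d


def _fingerprint(arrays: Mapping[str, np.ndarray | list | str]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        v = arrays[name]
        if isinstance(v, np.ndarray):
            h.update(np.ascontiguousarray(v).tobytes())
        else:
            h.update(json.dumps(v, sort_keys=True, default=str).encode())
    return h.hexdigest()


def run_delineation(
    ft: FrequencyTable,
    cov: CoverageSummary,
    meta: SampleMetadata,
    run_cfg: RunConfig = RunConfig(),
    outdir: str | Path = "subspec_run",
) -> dict[str, SubspeciesModel]:
    """Delineate subspecies for every eligible species and serialize models.

    Returns the fitted models keyed by species id; species failing the
    eligibility or delineation step are reported in the manifest with
    reasons rather than silently dropped.  Outputs are written only after
    all species have been processed (atomicity on bad inputs).
    """
    candidates = (
        list(run_cfg.species)
        if run_cfg.species is not None
        else eligible_species(cov, run_cfg.discovery)
    )
    eligible = set(eligible_species(cov, run_cfg.discovery))
    models: dict[str, SubspeciesModel] = {}
    failures: dict[str, str] = {}
    for sp in candidates:
        if sp not in eligible:
            failures[sp] = "fewer discovery samples than required"
            continue
        disco = select_discovery_samples(cov, sp, run_cfg.discovery)
        sub = ft.restrict_species(sp)
        if sub.n_positions == 0:
            failures[sp] = "no variant positions in frequency table"
            continue
        disco = [s for s in disco if s in sub.samples]
        try:
            filt = filter_positions(sub, disco, run_cfg.discovery)
            dcfg = dataclasses.replace(run_cfg.delineation, seed=run_cfg.seed)
            model = delineate(filt, meta, dcfg, cov=cov)
            if model.k >= 2:
                model.genotyping_positions = genotyping_positions(
                    filt, model, run_cfg.delta_threshold
                )
            models[sp] = model
        except ValueError as exc:
            failures[sp] = str(exc)
    if not models:
        raise ValueError(f"no species could be delineated: {failures}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, model in models.items():
        write_model(model, out / f"model_{sp}.json")
    manifest = {
        "tool": "subspec",
        "version": __version__,
        "stage": "delineation",
        "config": run_cfg.to_dict(),
        "seed": run_cfg.seed,
        "inputs": _fingerprint(
            {
                "freq": ft.freq,
                "samples": ft.samples,
                "positions": [str(p) for p in ft.positions],
                "coverage": cov.table.to_csv(index=False),
                "metadata": meta.table.to_csv(index=False),
            }
        ),
        "species": {
            sp: {"k": m.k, "n_samples": len(m.assignments)} for sp, m in models.items()
        },
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return models


def run_profile(
    ft_new: FrequencyTable,
    models: Mapping[str, SubspeciesModel],
    species_abund: AbundanceTable | None = None,
    run_cfg: RunConfig = RunConfig(),
    outdir: str | Path = "subspec_run",
) -> dict[str, SubspeciesProfile]:
    """Quantify subspecies of every modeled species in a cohort.

    Species present in the cohort but lacking a model (or a model without
    genotyping positions) are reported, not errors; an explicitly requested
    species without a model is an error.
    """
    profiles: dict[str, SubspeciesProfile] = {}
    skipped: dict[str, str] = {}
    wanted = list(run_cfg.species) if run_cfg.species is not None else list(models)
    if run_cfg.species is not None:
        missing = [sp for sp in wanted if sp not in models]
        if missing and len(missing) == len(wanted):
            raise ValueError(f"no model for requested species: {missing}")
        for sp in missing:
            skipped[sp] = "no fitted model"
            logger.warning("species %s requested but no model available", sp)
        wanted = [sp for sp in wanted if sp in models]
    for sp in wanted:
        model = models[sp]
        if model.k < 2 or model.genotyping_positions is None:
            skipped[sp] = "model has no subspecies structure"
            continue
        sub = ft_new.restrict_species(sp)
        if sub.n_positions == 0:
            skipped[sp] = "species absent from cohort frequency table"
            continue
        abund = None
        if species_abund is not None and sp in species_abund.taxa:
            row = species_abund.table.loc[sp]
            abund = {s: float(row[s]) for s in sub.samples if s in row.index}
        profiles[sp] = assign_cohort(
            sub,
            model.genotyping_positions,
            species_abundances=abund,
            sum_low=run_cfg.sum_low,
            sum_high=run_cfg.sum_high,
            dominance_threshold=run_cfg.dominance_threshold,
        )
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frames = [p.to_frame() for p in profiles.values()]
    if frames:
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(
            out / "profiles.tsv", sep="\t", index=False, float_format="%.10g"
        )
    summary = {
        "stage": "profile",
        "version": __version__,
        "config": run_cfg.to_dict(),
        "species": {
            sp: {
                "n_samples": len(p.entries),
                "n_assigned": sum(e.status == "assigned" for e in p.entries),
            }
            for sp, p in profiles.items()
        },
        "skipped": skipped,
    }
    with open(out / "profile_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return profiles
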