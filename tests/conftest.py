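"""Shared fixtures: small hand-built tables and cached simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from subspec.cluster import DelineationConfig, SubspeciesModel, delineate
from subspec.formats import (
    CoverageSummary,
    FrequencyTable,
    PositionKey,
    SampleMetadata,
)
from subspec.simulate import scenario, simulate_dataset


def make_positions(m: int, species: str = "sp1") -> list[PositionKey]:
    return [PositionKey(species, "contig1", i + 1, "A", "C") for i in range(m)]


def make_ft(freq, samples=None, species: str = "sp1", depth=None) -> FrequencyTable:
    """Frequency table from a (positions x samples) array (NaN = missing)."""
    freq = np.asarray(freq, dtype=float)
    if samples is None:
        samples = [f"s{j}" for j in range(freq.shape[1])]
    return FrequencyTable(
        positions=make_positions(freq.shape[0], species),
        samples=list(samples),
        freq=freq,
        depth=depth,
    )


def make_meta(samples, subjects=None, days=None, country="DE", study="study1", **extra):
    n = len(samples)
    df = pd.DataFrame(
        {
            "sample_id": list(samples),
            "subject_id": subjects if subjects is not None else [f"subj_{s}" for s in samples],
            "collection_day": days if days is not None else [0] * n,
            "country": country if isinstance(country, list) else [country] * n,
            "study": study if isinstance(study, list) else [study] * n,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return SampleMetadata(df)


def make_model(assignments: dict[str, str], species: str = "sp1") -> SubspeciesModel:
    """Model with medoids set to the first sample of each label."""
    medoids: dict[str, str] = {}
    for s, lab in assignments.items():
        medoids.setdefault(lab, s)
    k = len(set(assignments.values()))
    return SubspeciesModel(
        species_id=species,
        k=k,
        assignments=dict(assignments),
        medoids=medoids,
        ps_curve={2: 0.9},
        seed=0,
    )


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration (math.comb)."""
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


@pytest.fixture(scope="session")
def bench3():
    """Delineation benchmark dataset (k_true=3) plus its fitted model."""
    ds = simulate_dataset(scenario("delineation-bench", k_true=3, seed=7))
    model = delineate(ds.frequency, ds.metadata, DelineationConfig(seed=7))
    return ds, model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
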