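"""PAM, prediction strength, k selection and end-to-end delineation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from subspec.cluster import (
    DelineationConfig,
    choose_k,
    deduplicate_subjects,
    delineate,
    pam,
    pam_objective,
    prediction_strength,
)
from subspec.distance import DistanceMatrix
from subspec.formats import CoverageSummary
from subspec.simulate import SimulationConfig, simulate_dataset

from conftest import make_ft, make_meta


def square_dm(d):
    n = d.shape[0]
    return DistanceMatrix(
        samples=[f"s{i}" for i in range(n)], d=d,
        n_shared=np.full((n, n), 10**6), min_positions=1,
    )


class TestDeduplication:
    def test_earliest_day_kept(self):
        meta = make_meta(["a", "b"], subjects=["x", "x"], days=[200, 0])
        assert deduplicate_subjects(["a", "b"], meta) == ["b"]

    def test_day_ties_broken_by_sample_id(self):
        meta = make_meta(["b", "a"], subjects=["x", "x"], days=[0, 0])
        assert deduplicate_subjects(["b", "a"], meta) == ["a"]

    def test_singletons_unchanged(self):
        meta = make_meta(["a", "b", "c"])
        assert deduplicate_subjects(["a", "b", "c"], meta) == ["a", "b", "c"]

    def test_deepest_rule_uses_vertical_coverage(self):
        meta = make_meta(["a", "b"], subjects=["x", "x"], days=[0, 200])
        cov = CoverageSummary(
            pd.DataFrame(
                {"sample_id": ["a", "b"], "species_id": ["sp1", "sp1"],
                 "vertical": [5.0, 30.0], "horizontal": [0.9, 0.9]}
            )
        )
        got = deduplicate_subjects(["a", "b"], meta, rule="deepest",
                                   cov=cov, species_id="sp1")
        assert got == ["b"]

    def test_unknown_samples_listed_in_error(self):
        meta = make_meta(["a"])
        with pytest.raises(ValueError, match="ghost"):
            deduplicate_subjects(["a", "ghost"], meta)


class TestPam:
    def test_duplicated_profiles_recovered_exactly(self, rng):
        base = np.array([[0.0] * 5, [1.0] * 5])
        d = np.abs(base[:, None, :] - base[None, :, :]).mean(-1)
        groups = [0, 0, 0, 1, 1, 1]
        dd = d[np.ix_(groups, groups)]
        med, labels = pam(dd, 2)
        assert len({labels[i] for i in range(3)}) == 1
        assert len({labels[i] for i in range(3, 6)}) == 1
        assert labels[0] != labels[3]

    def test_swap_never_worse_than_build(self, rng):
        from subspec.cluster import _pam_core

        for _ in range(10):
            d = rng.random((15, 15))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            med, _ = _pam_core(d, 3)
            # BUILD-only objective: rerun BUILD by truncating SWAP via k medoids
            build = [int(np.argmin(d.sum(1)))]
            d1 = d[build[0]].copy()
            while len(build) < 3:
                gains = np.maximum(d1[None, :] - d, 0).sum(1)
                gains[build] = -np.inf
                j = int(np.argmax(gains))
                build.append(j)
                d1 = np.minimum(d1, d[j])
            assert pam_objective(d, list(med)) <= pam_objective(d, build) + 1e-12

    def test_matches_exhaustive_search(self, rng):
        for _ in range(20):
            d = rng.random((7, 7))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            med, _ = pam(d, 2)
            best = min(
                pam_objective(d, list(c)) for c in itertools.combinations(range(7), 2)
            )
            assert pam_objective(d, med) == pytest.approx(best, abs=1e-12)

    def test_k_bounds_enforced(self, rng):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            pam(d, 4)
        with pytest.raises(ValueError):
            pam(d, 0)


class TestPredictionStrength:
    def test_k1_is_one_by_definition(self, rng):
        d = rng.random((10, 10))
        assert prediction_strength(square_dm((d + d.T) / 2), 1) == 1.0

    def test_two_point_masses_perfectly_predictable(self):
        d = np.full((60, 60), 0.5)
        d[:30, :30] = 0.0
        d[30:, 30:] = 0.0
        np.fill_diagonal(d, 0)
        assert prediction_strength(square_dm(d), 2, seed=0) == 1.0

    def test_unstructured_profiles_score_low(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            freq = rng.random((300, 60))
            d = np.abs(freq[:, :, None] - freq[:, None, :]).mean(0)
            low += prediction_strength(square_dm(d), 2, seed=seed) < 0.8
        assert low >= 18  # >= 90% of runs

    def test_half_too_small_rejected(self):
        d = np.zeros((5, 5))
        with pytest.raises(ValueError):
            prediction_strength(square_dm(d), 3)


class TestChooseK:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ({2: 0.95, 3: 0.85, 4: 0.50}, 3),
            ({2: 0.79, 3: 0.70}, 1),   # conservative: no support -> one subspecies
            ({2: 0.81}, 2),
            ({2: 0.80}, 1),            # strictly above the threshold
        ],
    )
    def test_highest_supported_k(self, curve, expected):
        assert choose_k(curve) == expected


class TestDelineation:
    def test_recovers_k3_with_high_agreement(self, bench3):
        from sklearn.metrics import adjusted_rand_score

        ds, model = bench3
        assert model.k == 3
        truth = dict(zip(ds.frequency.samples, ds.truth.dominant_labels))
        samples = list(model.assignments)
        ari = adjusted_rand_score(
            [truth[s] for s in samples], [model.assignments[s] for s in samples]
        )
        assert ari >= 0.95

    def test_unstructured_species_reports_k1(self):
        ds = simulate_dataset(
            SimulationConfig(k_true=1, n_samples=100, m_positions=2000, seed=3)
        )
        model = delineate(ds.frequency, ds.metadata, DelineationConfig(seed=3))
        assert model.k == 1
        assert set(model.assignments.values()) == {"MGSS1"}

    def test_same_seed_reproduces_model_exactly(self):
        ds = simulate_dataset(
            SimulationConfig(k_true=2, n_samples=80, m_positions=1500, seed=5)
        )
        cfg = DelineationConfig(seed=11, min_samples=50)
        m1 = delineate(ds.frequency, ds.metadata, cfg)
        m2 = delineate(ds.frequency, ds.metadata, cfg)
        assert m1.to_dict() == m2.to_dict()

    def test_labels_ordered_by_cluster_size(self, bench3):
        _, model = bench3
        sizes = [
            sum(1 for lab in model.assignments.values() if lab == f"MGSS{i}")
            for i in range(1, model.k + 1)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_samples_after_dedup_is_error(self):
        freq = np.full((1200, 10), 0.5)
        ft = make_ft(freq)
        meta = make_meta(ft.samples)
        with pytest.raises(ValueError, match="minimum"):
            delineate(ft, meta, DelineationConfig(min_samples=50))
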