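"""Fixation, switching, enrichment and blocked association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from subspec.genotype import ProfileEntry, SubspeciesProfile
from subspec.stats import (
    benjamini_hochberg,
    blocked_association,
    category_enrichment,
    fisher_exact_p,
    fixation_summary,
    geography_enrichment,
    odds_ratio,
    switching_events,
)

from conftest import exact_fisher_two_sided, make_ft, make_meta


def entry(sample, dominant=None, exclusive=False, assigned=True, freqs=None):
    if freqs is None:
        labs = ["MGSS1", "MGSS2"]
        if dominant is None:
            freqs = {"MGSS1": 0.5, "MGSS2": 0.5}
        else:
            share = 1.0 if exclusive else 0.96
            freqs = {lab: (share if lab == dominant else 1 - share) for lab in labs}
    e = ProfileEntry(
        sample_id=sample, frequencies=freqs,
        status="assigned" if assigned else "unassigned",
    )
    e.dominant, e.exclusive = dominant, exclusive
    return e


def profile(entries):
    return SubspeciesProfile(species_id="sp1", entries=entries)


class TestFixationSummary:
    def test_direct_count(self):
        ft = make_ft(np.array([[0.01], [0.99], [0.50]]))
        assert fixation_summary(ft).iloc[0] == pytest.approx(2 / 3)

    def test_all_zero_frequencies_fully_fixed(self):
        ft = make_ft(np.zeros((5, 2)))
        assert (fixation_summary(ft) == 1.0).all()

    def test_boundaries_are_strict(self):
        ft = make_ft(np.array([[0.05], [0.95]]))
        assert fixation_summary(ft).iloc[0] == 0.0

    def test_uncovered_sample_is_missing(self):
        ft = make_ft(np.full((3, 1), np.nan))
        assert np.isnan(fixation_summary(ft).iloc[0])


class TestSwitchingEvents:
    def test_single_dominance_change_counted_once(self):
        ents = [entry("a", "MGSS1", True), entry("b", "MGSS1", True),
                entry("c", "MGSS2", True)]
        meta = make_meta(["a", "b", "c"], subjects=["x"] * 3, days=[0, 100, 200])
        n, recs = switching_events(profile(ents), meta)
        assert n == 1
        assert [r.is_switch for r in recs] == [True]

    def test_undefined_dominance_is_boundary_not_switch(self):
        ents = [entry("a", "MGSS1", True), entry("b", assigned=False),
                entry("c", "MGSS1", True)]
        meta = make_meta(["a", "b", "c"], subjects=["x"] * 3, days=[0, 100, 200])
        n, recs = switching_events(profile(ents), meta)
        assert n == 0
        assert len(recs) == 2 and not any(r.is_switch for r in recs)

    def test_mixed_baseline_flagged(self):
        ents = [entry("a", "MGSS1", exclusive=False), entry("b", "MGSS2", True)]
        meta = make_meta(["a", "b"], subjects=["x"] * 2, days=[0, 200])
        _, recs = switching_events(profile(ents), meta)
        assert recs[0].baseline_mixed

    def test_tied_days_rejected(self):
        ents = [entry("a", "MGSS1", True), entry("b", "MGSS1", True)]
        meta = make_meta(["a", "b"], subjects=["x"] * 2, days=[5, 5])
        with pytest.raises(ValueError, match="tied"):
            switching_events(profile(ents), meta)


class TestEnrichment:
    def test_strong_contingency_hand_checked(self):
        # 20 of 25 dominant-in-country are MGSS1 vs 5 of 25 elsewhere
        ents = (
            [entry(f"a{i}", "MGSS1", True) for i in range(20)]
            + [entry(f"b{i}", "MGSS2", True) for i in range(5)]
            + [entry(f"c{i}", "MGSS1", True) for i in range(5)]
            + [entry(f"d{i}", "MGSS2", True) for i in range(20)]
        )
        samples = [e.sample_id for e in ents]
        meta = make_meta(samples, country=["DK"] * 25 + ["ES"] * 25)
        res = geography_enrichment(profile(ents), meta, min_samples_per_country=5)
        hit = next(r for r in res if r.unit == ("MGSS1", "DK"))
        assert hit.table == ((20, 5), (5, 20))
        assert hit.odds_ratio == pytest.approx(16.0)
        assert hit.p_value == pytest.approx(exact_fisher_two_sided(20, 5, 5, 20))

    def test_identical_composition_yields_no_discoveries(self):
        ents = (
            [entry(f"a{i}", "MGSS1", True) for i in range(15)]
            + [entry(f"b{i}", "MGSS2", True) for i in range(15)]
            + [entry(f"c{i}", "MGSS1", True) for i in range(15)]
            + [entry(f"d{i}", "MGSS2", True) for i in range(15)]
        )
        samples = [e.sample_id for e in ents]
        meta = make_meta(samples, country=["DK"] * 30 + ["ES"] * 30)
        res = geography_enrichment(profile(ents), meta)
        assert all(r.p_value == pytest.approx(1.0) for r in res)
        assert not any(r.q_value < 0.05 for r in res)

    def test_null_type_one_error_control(self, rng):
        families_with_hit = 0
        for _ in range(40):
            doms = rng.choice(["MGSS1", "MGSS2"], size=60)
            ents = [entry(f"s{i}", doms[i], True) for i in range(60)]
            meta = make_meta([e.sample_id for e in ents],
                             country=["DK"] * 30 + ["ES"] * 30)
            res = geography_enrichment(profile(ents), meta)
            families_with_hit += any(r.q_value < 0.05 for r in res)
        assert families_with_hit <= 3

    def test_zero_cell_gets_haldane_odds_only(self):
        table = ((10, 0), (5, 85))
        assert odds_ratio(table) == pytest.approx((10.5 * 85.5) / (0.5 * 5.5))
        assert fisher_exact_p(table) == pytest.approx(
            exact_fisher_two_sided(10, 0, 5, 85)
        )

    def test_category_only_in_sssc(self):
        sssc = {f"g{i}" for i in range(10)}
        sc = {f"h{i}" for i in range(100)}
        ann = pd.DataFrame(
            {"gene_id": list(sssc) + list(sc),
             "category": ["phage"] * 10 + ["other"] * 100}
        )
        res = category_enrichment(sssc, sc, ann)
        hit = next(r for r in res if r.unit[1] == "phage")
        assert hit.table == ((10, 0), (0, 100))
        assert hit.p_value == pytest.approx(exact_fisher_two_sided(10, 0, 0, 100))

    def test_identical_category_rates_not_significant(self):
        sssc = {f"g{i}" for i in range(10)}
        sc = {f"h{i}" for i in range(20)}
        ann = pd.DataFrame(
            {"gene_id": list(sssc) + list(sc),
             "category": ["x"] * 5 + ["y"] * 5 + ["x"] * 10 + ["y"] * 10}
        )
        res = category_enrichment(sssc, sc, ann)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_empty_universe_is_error(self):
        ann = pd.DataFrame({"gene_id": ["z"], "category": ["x"]})
        with pytest.raises(ValueError):
            category_enrichment({"a"}, {"b"}, ann)


class TestBenjaminiHochberg:
    def test_hand_computed_fixture(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.2])
        assert np.allclose(q, [0.05, 0.05, 0.05, 0.05, 0.2])

    def test_q_monotone_and_at_least_p(self, rng):
        p = rng.random(50)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestBlockedAssociation:
    def _profile_meta(self, values, groups, studies):
        ents = [entry(f"s{i}", g, True) for i, g in enumerate(groups)]
        meta = make_meta([e.sample_id for e in ents], study=list(studies),
                         bmi=list(values))
        return profile(ents), meta

    def test_single_stratum_matches_exact_wilcoxon(self, rng):
        diffs = []
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            values = np.concatenate([x, y])
            groups = ["MGSS1"] * 8 + ["MGSS2"] * 8
            prof, meta = self._profile_meta(values, groups, ["st"] * 16)
            res = blocked_association(prof, meta, "bmi", n_perm=4999, seed=1)
            p_exact = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            diffs.append(abs(res.p_value - p_exact))
        assert np.mean(diffs) < 0.01 and max(diffs) < 0.04

    def test_confounded_study_effect_not_detected(self, rng):
        # subspecies composition differs by study; phenotype tracks study only
        groups = ["MGSS1"] * 24 + ["MGSS2"] * 6 + ["MGSS1"] * 6 + ["MGSS2"] * 24
        studies = ["A"] * 30 + ["B"] * 30
        values = np.r_[rng.normal(0, 1, 30), rng.normal(2.0, 1, 30)]
        prof, meta = self._profile_meta(values, groups, studies)
        res = blocked_association(prof, meta, "bmi", n_perm=1999, seed=3)
        assert res.p_value > 0.05

    def test_one_group_stratum_dropped_with_warning(self, caplog):
        groups = ["MGSS1"] * 5 + ["MGSS2"] * 5 + ["MGSS1"] * 4
        studies = ["A"] * 10 + ["B"] * 4
        values = list(range(14))
        prof, meta = self._profile_meta(values, groups, studies)
        with caplog.at_level("WARNING"):
            res = blocked_association(prof, meta, "bmi", n_perm=499, seed=0)
        assert res.dropped_strata == ["B"]

    def test_all_strata_dropped_is_error(self):
        groups = ["MGSS1"] * 5 + ["MGSS2"] * 5
        studies = ["A"] * 5 + ["B"] * 5
        prof, meta = self._profile_meta(list(range(10)), groups, studies)
        with pytest.raises(ValueError, match="strata"):
            blocked_association(prof, meta, "bmi", n_perm=99)

    def test_inclusion_requires_dominance(self):
        # a 60/40 sample must not enter the 95%-dominance association test
        ents = [entry(f"s{i}", "MGSS1", True) for i in range(5)]
        ents += [entry(f"t{i}", "MGSS2", True) for i in range(5)]
        mixed = entry("mix", "MGSS1", freqs={"MGSS1": 0.6, "MGSS2": 0.4})
        prof = profile(ents + [mixed])
        meta = make_meta([e.sample_id for e in prof.entries],
                         bmi=list(range(11)))
        res = blocked_association(prof, meta, "bmi", n_perm=199, seed=0)
        n_used = sum(sum(v.values()) for v in res.n_per_group_per_stratum.values())
        assert n_used == 10
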