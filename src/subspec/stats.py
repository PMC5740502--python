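"""Downstream statistics on subspecies profiles.

Covers: per-sample allele-fixation summaries; temporal switching of the
dominant subspecies within subjects; geographic enrichment of subspecies
(Fisher exact tests, Benjamini-Hochberg FDR); enrichment of functional
categories in subspecies-specific cores versus species cores; and blocked
(study-stratified) permutation tests associating subspecies dominance with
host phenotypes (van Elteren-style sum of standardized within-stratum
rank-sum statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .formats import FrequencyTable, SampleMetadata
from .genotype import SubspeciesProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "AssociationResult",
    "SwitchRecord",
    "fixation_summary",
    "switching_events",
    "geography_enrichment",
    "category_enrichment",
    "blocked_association",
    "benjamini_hochberg",
    "odds_ratio",
]

FIXED_LOW = 0.05
FIXED_HIGH = 0.95
ASSOCIATION_DOMINANCE = 0.95  # inclusion threshold, distinct from dominance (0.9)
DEFAULT_N_PERM = 10_000


@dataclass
class EnrichmentResult:
    """One 2x2 Fisher test with FDR-corrected p-value."""

    unit: tuple[str, str]  # (subspecies, country) or (core set, category)
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log_odds: float
    p_value: float
    q_value: float = np.nan


@dataclass
class AssociationResult:
    """Blocked rank-sum association between subspecies and a phenotype."""

    species_id: str
    phenotype: str
    groups: tuple[str, str]
    statistic: float
    p_value: float
    q_value: float = np.nan
    n_per_group_per_stratum: dict[str, dict[str, int]] = field(default_factory=dict)
    n_perm: int = 0
    dropped_strata: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SwitchRecord:
    subject_id: str
    species_id: str
    day_from: float
    day_to: float
    label_from: str | None
    label_to: str | None
    is_switch: bool  # both labels defined and different
    baseline_mixed: bool  # subject had co-occurring subspecies at baseline


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table."""
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def odds_ratio(table: np.ndarray, haldane: bool = True) -> float:
    """Sample odds ratio of a 2x2 table, +0.5 in every cell when any is 0."""
    a, b = float(table[0][0]), float(table[0][1])
    c, d = float(table[1][0]), float(table[1][1])
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# allele fixation


def fixation_summary(
    ft: FrequencyTable, low: float = FIXED_LOW, high: float = FIXED_HIGH
) -> pd.Series:
    """Per-sample fraction of covered positions with fixed alleles.

    An allele is "fixed" when its frequency is strictly below ``low`` or
    strictly above ``high``.  Samples with no covered positions get NaN.
    """
    valid = ~np.isnan(ft.freq)
    with np.errstate(invalid="ignore"):
        fixed = ((ft.freq < low) | (ft.freq > high)) & valid
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, fixed.sum(axis=0) / np.maximum(n_valid, 1), np.nan)
    return pd.Series(frac, index=ft.samples, name="fixed_fraction")


# ---------------------------------------------------------------------------
# temporal switching


def switching_events(
    profiles: SubspeciesProfile, meta: SampleMetadata
) -> tuple[int, list[SwitchRecord]]:
    """Count changes of the dominant subspecies along subjects' time series.

    Consecutive time points with two different dominant labels count as one
    switch; transitions into or out of an undefined dominance state
    (unassigned sample or no dominant subspecies) are recorded but not
    counted.  Each record flags whether the subject's earliest sample had
    co-occurring subspecies (a dominant that was not exclusive, or none).
    """
    msub = meta.table.set_index("sample_id")
    by_subject: dict[str, list] = {}
    for e in profiles.entries:
        if e.sample_id not in msub.index:
            raise ValueError(f"sample {e.sample_id} absent from metadata")
        row = msub.loc[e.sample_id]
        by_subject.setdefault(str(row["subject_id"]), []).append(
            (float(row["collection_day"]), e)
        )
    records: list[SwitchRecord] = []
    n_switches = 0
    for subject, series in by_subject.items():
        if len(series) < 2:
            continue
        days = [d for d, _ in series]
        if len(set(days)) != len(days):
            raise ValueError(f"subject {subject}: tied collection days {days}")
        series.sort(key=lambda t: t[0])
        first = series[0][1]
        baseline_mixed = not (first.status == "assigned" and first.exclusive)
        for (day_a, ea), (day_b, eb) in zip(series, series[1:]):
            lab_a = ea.dominant if ea.status == "assigned" else None
            lab_b = eb.dominant if eb.status == "assigned" else None
            is_switch = lab_a is not None and lab_b is not None and lab_a != lab_b
            if is_switch or lab_a != lab_b:
                records.append(
                    SwitchRecord(
                        subject_id=subject,
                        species_id=profiles.species_id,
                        day_from=day_a,
                        day_to=day_b,
                        label_from=lab_a,
                        label_to=lab_b,
                        is_switch=is_switch,
                        baseline_mixed=baseline_mixed,
                    )
                )
            if is_switch:
                n_switches += 1
    return n_switches, records


# ---------------------------------------------------------------------------
# geographic enrichment


def geography_enrichment(
    profiles: SubspeciesProfile,
    meta: SampleMetadata,
    min_samples_per_country: int = 10,
) -> list[EnrichmentResult]:
    """Per subspecies x country over-representation of dominance.

    One sample per subject (earliest) is counted to avoid pseudo-
    replication; only samples with a dominant subspecies enter.  For every
    subspecies and country a 2x2 table contrasts dominance in the country
    vs elsewhere against this subspecies vs its conspecific others; p from
    the two-sided Fisher exact test, BH-corrected across all tests of the
    species.  Odds ratios are Haldane-corrected when any cell is zero.
    """
    msub = meta.table.set_index("sample_id")
    rows = []
    for e in profiles.entries:
        if e.status != "assigned" or e.dominant is None:
            continue
        mrow = msub.loc[e.sample_id]
        rows.append(
            {
                "sample_id": e.sample_id,
                "subject_id": mrow["subject_id"],
                "collection_day": float(mrow["collection_day"]),
                "country": str(mrow["country"]),
                "dominant": e.dominant,
            }
        )
    if not rows:
        return []
    df = pd.DataFrame(rows).sort_values(["collection_day", "sample_id"])
    df = df.drop_duplicates(subset="subject_id", keep="first")
    counts = df.groupby("country").size()
    small = counts[counts < min_samples_per_country].index.tolist()
    if small:
        logger.info("countries below %d samples excluded: %s",
                    min_samples_per_country, small)
        df = df[~df["country"].isin(small)]
    labels = sorted(df["dominant"].unique())
    countries = sorted(df["country"].unique())
    results: list[EnrichmentResult] = []
    for lab in labels:
        for country in countries:
            a = int(((df["dominant"] == lab) & (df["country"] == country)).sum())
            b = int(((df["dominant"] != lab) & (df["country"] == country)).sum())
            c = int(((df["dominant"] == lab) & (df["country"] != country)).sum())
            d = int(((df["dominant"] != lab) & (df["country"] != country)).sum())
            table = ((a, b), (c, d))
            p = fisher_exact_p(table)
            orr = odds_ratio(table)
            results.append(
                EnrichmentResult(
                    unit=(lab, country),
                    table=table,
                    odds_ratio=orr,
                    log_odds=float(np.log(orr)),
                    p_value=p,
                )
            )
    q = benjamini_hochberg([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def max_significant_log_odds(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> dict[str, float]:
    """Per country, the maximum log-odds ratio among significant subspecies
    enrichments (q < alpha) of one species."""
    out: dict[str, float] = {}
    for r in results:
        if r.q_value < alpha:
            _, country = r.unit
            out[country] = max(out.get(country, -np.inf), r.log_odds)
    return out


# ---------------------------------------------------------------------------
# functional category enrichment


def category_enrichment(
    sssc_genes: set[str],
    sc_genes: set[str],
    annotations: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Fisher tests for category enrichment in SSSC versus SC gene sets.

    ``annotations`` has columns ``gene_id`` and ``category`` (optionally
    ``source``; BH correction is applied within each source).  Unannotated
    genes are excluded from the universe.  The same contrast applies to any
    two disjoint gene sets (e.g., SSSC vs conspecific SSSC).
    """
    ann = annotations.copy()
    if "source" not in ann.columns:
        ann["source"] = "default"
    universe = (sssc_genes | sc_genes) & set(ann["gene_id"])
    if not universe:
        raise ValueError("no annotated genes in either gene set")
    ann = ann[ann["gene_id"].isin(universe)]
    n_sssc = len(sssc_genes & universe)
    n_sc = len(sc_genes & universe)
    results: list[EnrichmentResult] = []
    by_source: dict[str, list[int]] = {}
    for (source, category), grp in sorted(
        ann.groupby(["source", "category"]), key=lambda t: (str(t[0][0]), str(t[0][1]))
    ):
        cat_genes = set(grp["gene_id"])
        a = len(cat_genes & sssc_genes)
        b = n_sssc - a
        c = len(cat_genes & sc_genes)
        d = n_sc - c
        table = ((a, b), (c, d))
        p = fisher_exact_p(table)
        orr = odds_ratio(table)
        by_source.setdefault(str(source), []).append(len(results))
        results.append(
            EnrichmentResult(
                unit=("SSSC_vs_SC", str(category)),
                table=table,
                odds_ratio=orr,
                log_odds=float(np.log(orr)),
                p_value=p,
            )
        )
    for source, idx in by_source.items():
        q = benjamini_hochberg([results[i].p_value for i in idx])
        for i, qv in zip(idx, q):
            results[i].q_value = float(qv)
    return results


# ---------------------------------------------------------------------------
# blocked host-phenotype association


def _stratum_z(values: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum statistic of one stratum (tie-corrected)."""
    ranks = sps.rankdata(values)
    n = values.size
    n1 = int(in_group.sum())
    w = float(ranks[in_group].sum())
    mean = n1 * (n + 1) / 2.0
    # exact permutation variance of the rank sum, valid under ties
    var = n1 * (n - n1) / (n * (n - 1)) * float(((ranks - (n + 1) / 2.0) ** 2).sum())
    if var <= 0:
        return 0.0
    return (w - mean) / np.sqrt(var)


def blocked_association(
    profiles: SubspeciesProfile,
    meta: SampleMetadata,
    phenotype: str,
    inclusion_dominance: float = ASSOCIATION_DOMINANCE,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> AssociationResult:
    """Stratified permutation rank-sum test of subspecies vs phenotype.

    Only samples dominated by one subspecies (share of the summed
    subspecies frequencies > ``inclusion_dominance``) are included.  The
    statistic is the sum over study strata of standardized within-stratum
    rank-sum statistics (van Elteren form); its null distribution is
    obtained by permuting subspecies labels within strata only, preserving
    study composition.  Binary phenotypes are handled by the same machinery
    (rank sums of a 0/1 variable).  Strata containing a single subspecies
    group are dropped with a warning.
    """
    msub = meta.table.set_index("sample_id")
    rows = []
    for e in profiles.entries:
        if e.status != "assigned":
            continue
        shares = e.shares
        top = max(shares, key=lambda lab: shares[lab])
        if shares[top] <= inclusion_dominance:
            continue
        mrow = msub.loc[e.sample_id]
        v = mrow.get(phenotype, np.nan)
        v = pd.to_numeric(pd.Series([v]), errors="coerce").iloc[0]
        if pd.isna(v):
            continue
        rows.append({"group": top, "study": str(mrow["study"]), "value": float(v)})
    if not rows:
        raise ValueError("no samples pass the dominance/phenotype filters")
    df = pd.DataFrame(rows)
    group_sizes = df.groupby("group").size().sort_values(ascending=False)
    if len(group_sizes) < 2:
        raise ValueError("fewer than two subspecies groups after filtering")
    g1, g2 = group_sizes.index[0], group_sizes.index[1]
    if len(group_sizes) > 2:
        logger.warning(
            "%s: %d groups present; contrasting the two largest (%s vs %s)",
            profiles.species_id, len(group_sizes), g1, g2,
        )
        df = df[df["group"].isin([g1, g2])]
    strata_vals: list[np.ndarray] = []
    strata_in: list[np.ndarray] = []
    dropped: list[str] = []
    n_table: dict[str, dict[str, int]] = {}
    for study, grp in df.groupby("study"):
        groups = set(grp["group"])
        if len(groups) < 2:
            dropped.append(str(study))
            logger.warning("stratum %s has one group only; dropped", study)
            continue
        strata_vals.append(grp["value"].to_numpy())
        strata_in.append((grp["group"] == g1).to_numpy())
        n_table[str(study)] = grp.groupby("group").size().to_dict()
    if not strata_vals:
        raise ValueError("all strata dropped (each contains one group only)")
    t_obs = sum(_stratum_z(v, m) for v, m in zip(strata_vals, strata_in))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t_perm = np.zeros(n_perm)
    for v, m in zip(strata_vals, strata_in):
        ranks = sps.rankdata(v)
        n = v.size
        n1 = int(m.sum())
        mean = n1 * (n + 1) / 2.0
        var = n1 * (n - n1) / (n * (n - 1)) * float(
            ((ranks - (n + 1) / 2.0) ** 2).sum()
        )
        if var <= 0:
            continue
        # vectorized within-stratum label permutations
        perm_ranks = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
        w = perm_ranks[:, :n1].sum(axis=1)
        t_perm += (w - mean) / np.sqrt(var)
    p = float((1 + np.sum(np.abs(t_perm) >= np.abs(t_obs) - 1e-12)) / (n_perm + 1))
    return AssociationResult(
        species_id=profiles.species_id,
        phenotype=phenotype,
        groups=(str(g1), str(g2)),
        statistic=float(t_obs),
        p_value=p,
        n_per_group_per_stratum=n_table,
        n_perm=n_perm,
        dropped_strata=dropped,
    )
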