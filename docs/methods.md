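# Methods

This note documents the models, numerical choices and design decisions
behind `subspec`, and what the simulation benchmarks do and do not show
about real data.

## The delineation model

The unit of analysis is one microbial species observed across many
metagenomic samples.  Each sample contributes a vector of non-reference
allele frequencies at the species' population-variant positions (fractions
in [0, 1], missing where the position is insufficiently covered).  The
underlying biological picture: each host carries one or a few strains of
the species; when strain genomes fall into a few diverged clades
(subspecies), samples dominated by different clades have near-opposite
allele profiles at clade-diagnostic positions, while allele frequencies
within a sample are mostly near 0 or 1 ("fixed") because a single strain
usually dominates.

**Distance.** Between two samples the package uses the normalized
Manhattan dissimilarity over pairwise-complete positions,
`d = Σ|S1ᵢ − S2ᵢ|/n`.  Missing entries are excluded pairwise, never
imputed.  A pair must share at least `min_positions` (default 1000)
covered positions; the underlying count is kept alongside the distance.
The source description of this threshold is ambiguous between a strict
and non-strict reading; the package uses `n ≥ min_positions`, and the
parameter is configurable.  PAM requires a complete matrix, so samples
with invalid pairs are greedily removed (most-missing first, ties by
sample id) — a pragmatic completion rule, logged sample by sample.

**Clustering and model selection.** PAM is implemented as BUILD plus
steepest-descent SWAP with deterministic lowest-index tie-breaking; tiny
instances (≤ 2000 candidate medoid sets) are solved exactly by
enumeration, which removes the rare local optima of the swap heuristic at
negligible cost.  Cluster support is quantified by prediction strength:
the data are split 50/50; both halves are clustered; test samples are
classified to their nearest training medoid; the split scores the minimum
over test clusters of the fraction of within-cluster pairs co-assigned by
that classification (singleton clusters have no pairs and contribute 1).
The split scheme is not fixed by the original prediction-strength
formulation; `subspec` averages 25 seeded random splits, which is more
stable than a single split.  Each candidate k draws its splits from an
independent seed stream, so the curve does not depend on `k_max`.  The
chosen number of subspecies is the highest k with mean PS strictly above
0.8; if none qualifies the species is reported as unstructured (k = 1) —
a deliberately conservative rule.  Cluster labels MGSS1…MGSSk are
assigned by decreasing cluster size (ties by medoid id) purely for
reproducibility; the numbering carries no meaning.

**Genotyping positions and quantification.** For subspecies s, a position
qualifies when `mean_in − mean_out > 0.8`, where `mean_in` averages over
samples assigned to s (missing excluded) and `mean_out` pools all other
assigned samples (not a per-cluster average — "the rest" is one group).
The delta is signed: a genotyping position marks the subspecies whose
non-reference allele is enriched; there are no reverse-orientation
positions.  A sample's subspecies frequency is the median over covered
genotyping positions, which is robust to a minority of discordant
positions by construction.  Frequencies summing outside [0.8, 1.2] leave
the sample unassigned (reported, never dropped); missing coverage for
every subspecies gives an explicit "no coverage" status, and a subspecies
with zero genotyping positions is flagged rather than guessed at.
Dominance (> 0.9 of the summed frequencies) and the association-inclusion
threshold (> 0.95) are deliberately distinct named constants.

**Ordination.** Classical scaling (double-centered −½D², `scipy`
eigendecomposition).  The Manhattan-type distance is not Euclidean, so
negative eigenvalues occur; they are dropped and their mass reported, not
corrected (no Cailliez/Lingoes) — corrections change coordinates without
changing any downstream decision here.  Out-of-sample points (new samples
or reference-genome allele profiles) enter through Gower's formula from
their distances to the training samples; projecting a training row
reproduces its coordinates, which is tested.  Genome placement uses exact
allele profiles (1 at carried alternative alleles, 0 at reference,
missing where uncovered), the noiseless limit of placing a genome via
simulated reads.

**Gene content.** Co-abundance binning: Pearson on log10-transformed
relative abundances (> 0.8) and Spearman on raw values (> 0.6), computed
over samples where the target taxon is detected (> 0) — shared absences
would otherwise inflate correlations.  Zeros are offset by half the
smallest nonzero value of the respective table before log transformation.
A gene is assigned to the passing target with the highest Pearson r
(ties: Spearman, then lexicographic id); both thresholds must hold for a
candidate to be considered at all, the stricter reading of an ambiguous
rule.

**Statistics.** Fixation uses strict bounds (< 0.05, > 0.95).  Dominance
switching counts only transitions between two defined dominant labels;
transitions into or out of undefined dominance are recorded separately —
an undefined state is not a subspecies.  Geographic and functional
enrichment use the two-sided Fisher exact test with Benjamini–Hochberg
correction per species (geography) or per annotation source (categories);
odds ratios get the Haldane +0.5 correction only when a cell is zero, the
p-value stays exact.  Geography counts one sample per subject to avoid
pseudo-replication.  Host-phenotype association uses a van Elteren-style
statistic — the sum over study strata of standardized within-stratum
Wilcoxon rank-sum statistics, with the exact tie-corrected permutation
variance — and a null distribution from permuting subspecies labels
within strata only (default 10,000 permutations, seedable;
`p = (1 + #{|T*| ≥ |T|})/(n_perm + 1)`).  Stratification is what removes
between-study batch effects; the calibration benchmark (below) verifies
it.  The statistic is two-group; when more than two subspecies pass the
95%-dominance inclusion filter the two largest groups are contrasted and
a warning is logged.  Binary phenotypes run through the same machinery
(rank sums of a 0/1 variable), equivalent to a stratified test of
proportions.

## The simulator

`subspec.simulate` generates the statistical structure the method
assumes, with full ground truth:

* `k_true` haplotypes over `m_positions`, pairwise divergent at a
  `divergence` fraction of positions (each discriminating position flips
  one haplotype, so pairwise divergence is calibrated for any k).
* Within-subspecies strain variation: a `strain_divergence` fraction of
  positions (default 0.02) segregate independently — each subject's
  strain draws its allele Bernoulli(0.5) there.  This keeps within-sample
  alleles fixed at 0/1 (matching the observed fixation of most variants)
  while giving conspecific samples a realistic nonzero dissimilarity
  (~0.01) with no artificial geometry.  A per-sample mutation-rate model
  was rejected because it produces additive "star" distances on which
  medoid clustering degenerates; independent segregating sites do not.
* Mixtures: with probability `mixture_prob` (default 0.17, the complement
  of the observed 83% exclusivity) a subject carries two subspecies, the
  minor at a fraction uniform on (0, `mixture_minor_max` = 0.15].  The
  bounded minor fraction mirrors the observation that one subspecies
  generally holds > 90% of within-sample abundance; unbounded mixture
  weights would scatter samples between clusters and create spurious
  stable clusters no real dataset shows.
* Reads: depth ~ Poisson(`coverage_mean`) per position and sample,
  observed frequency ~ Binomial(depth, true)/depth, missing at zero depth
  or with `missing_rate`.  There is no separate sequencing-error model —
  at the frequencies involved it would be absorbed by the binomial noise.
  `infinite_depth=True` gives the noiseless limit used by exactness
  tests.
* Abundances: species lognormal (log10 mean −1, sd 0.5); SC genes track
  the species and SSSC genes their subspecies, each with lognormal noise
  of `gene_noise_sd` (log10).
* Metadata: subjects × time points (`day_gap` apart, default 200 days),
  country-biased subspecies priors, per-study phenotype shifts, a
  per-subspecies phenotype effect in SD units, and an optional forced
  dominant-subspecies replacement at `switch_day`.

What the simulator does **not** emulate: linkage between variant
positions beyond haplotype membership, recombination and horizontal
transfer, within-subspecies phylogenetic (nested) structure, read-mapping
artifacts, compositionality of abundance profiles, and uneven
per-position coverage biases.  Passing benchmarks therefore demonstrate
correctness of the algorithms under the stated generative assumptions,
not performance guarantees on arbitrary real cohorts.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run at sizes chosen to make
every stochastic criterion stable yet quick: the delineation benchmark
uses n = 200 samples × m = 5000 positions at 10× coverage with 5%
haplotype divergence, 20 seeds per k ∈ {1, 2, 3, 4}; genotyping and
mixture benchmarks use 100–150 samples × 2000–3000 positions at 20×; the
gene-content benchmark plants 100 SC + 2 × 60 SSSC genes with 0.15 log10
noise over 200 samples; association calibration runs 1000 simulated null
cohorts (n = 120, two confounded studies) at 999 permutations each and
power 100 cohorts at 1999; Fisher exactness enumerates all 2×2 tables
with margins ≤ 30 (deduplicated by symmetry) against a direct
hypergeometric oracle.

## Known limitations

* The completion rule for missing distances (greedy sample removal) is
  one of several defensible choices; with very sparse overlap it can
  remove many samples — thresholds should then be revisited.
* Prediction strength is insensitive to consistently-carved singleton
  clusters; extremely tight clusters plus isolated outliers can inflate
  k.  Real allele-frequency data and the bundled simulator both spread
  samples enough for the criterion to behave, but heavily filtered or
  deduplicated inputs may not.
* The association test contrasts two groups; multi-subspecies phenotype
  models (regression, mixed effects) are out of scope.
* Percent/fraction auto-detection assumes at least one value above 1 in
  percent-scaled input; an all-below-1% percent table would be misread —
  pass `scale_hint="percent"` in that case.
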