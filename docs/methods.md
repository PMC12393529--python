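# Methods

This note documents the models and procedures implemented in `symbiopan`,
the assumptions behind them, the parameters that matter, and the places
where the design was genuinely open and a choice had to be made.

## Scope and data model

The pipeline consumes Newick trees (a bacterial core-gene tree, host
cladograms, UPGMA dendrograms), binary gene-family × genome presence/absence
matrices (PIRATE/Roary-style Rtab or CSV), genome metadata (lifestyle,
optional host taxon/pigmentation/geography), square ANI similarity matrices,
binary host × symbiont association matrices, and read-recruitment count
tables. Upstream sequence work — annotation, orthology inference, alignment,
ML tree inference, fastANI itself, read QC and mapping — is out of scope;
those tools' outputs are the inputs here. Newick is written with `%.10g`
branch lengths and no root edge length, so read → write → read is the
identity to 10 significant digits. ANI tables with reciprocal asymmetry
≤ 1e-6 (fastANI is asymmetric by construction) are symmetrized by averaging;
larger asymmetry is an error. Similarity values above 1 are read as
percentages.

## Pangenome structure

A family present in exactly one genome of the subset under study is
*unique*; one whose prevalence strictly exceeds `core_threshold` (default
0.95, i.e. "present in more than 95% of genomes") is *core*; the rest are
*accessory*. Families absent from a lifestyle subset are dropped before
classification, so lifestyle-restricted pangenomes have independent totals.
Percentages are reported to two decimals and sum to 100 ± 0.01.

Accumulation curves average the cumulative number of distinct families over
seeded random genome orderings (default 100; an exhaustive mode enumerates
all n! orderings for n ≤ 8 and is used by the tests as an oracle anchor).
Openness is a reproducible numeric verdict standing in for the visual
asymptote judgment: fit log(mean) = log κ + γ·log N over N ≥ 3 and call the
pangenome open when γ > 0.02 **and** the last genome added still contributes
new families on average. The γ cutoff is config-exposed; it is a pragmatic
threshold, not an estimate of anything.

The gene-class × lifestyle association is a Pearson chi-square without
continuity correction on the 2 × 3 count table (df = 2). Expected cells
below 1 trigger a warning but not a failure.

## ANI phylogroups

Genomes are clustered by hierarchical agglomeration on 1 − ANI and the tree
is cut at 1 − threshold (default 0.95, the conventional species/phylogroup
boundary). Average linkage is the default — the secondary-clustering choice
of the dereplication tools this step mirrors; single linkage (equivalent to
connected components of the ≥-threshold graph, which the tests exploit as an
oracle) is offered. Phylogroup labels PG1…PGk are assigned by descending
cluster size with ties broken by the lexicographically smallest member, so
numbering is a deterministic function of the clustering alone. A phylogroup
is *mixed* when it contains both host-associated and free-living genomes.

## Accessory network

The accessory matrix is filtered to families with prevalence strictly above
`prevalence_filter` (default 0.05); core and unique families are excluded.
Genome–genome similarity is Jaccard over presence vectors by default
(simple matching offered; the upstream toolkit's exact metric is not
standardized), edges form at similarity ≥ `edge_threshold` (default 0.5,
config-exposed; display-side thresholds vary by tool), and isolated nodes
are retained. Whether the network is structured by lifestyle or by
phylogroup is quantified as the Newman categorical assortativity coefficient
over edge weights — a numeric stand-in for what is usually judged from a
network layout by eye.

## Cophylogeny statistics

**Patristic distances and PCoA.** Principal coordinates are computed from
the double-centered Gram matrix of squared distances. Patristic distances
are frequently non-Euclidean, so the Cailliez correction (adding the
smallest constant to off-diagonal distances making the configuration
Euclidean, found from the 2n × 2n companion eigenproblem) is the default;
Lingoes (constant added to squared distances) and no correction are
available. Axes with eigenvalue > 1e-9 are retained; Euclidean distances
among the returned coordinates reproduce the corrected inputs to 1e-6.

**PACo.** Both embeddings are expanded over the association links (one row
per link), column-centered, and scaled to unit trace. With both
configurations unit-norm, the residual after the optimal rotation and
scaling is m² = 1 − (Σσ)², guaranteed in [0, 1], so R² = 1 − m² is well
defined; this symmetric scaling is required for the R² formula to make
sense. Significance is by permutation of the association with the add-one
estimator p = (1 + #{m²_perm ≤ m²_obs}) / (n + 1); ties count as ≤; the
default is 1000 permutations. Degenerate permuted configurations (all
coordinates identical after link expansion) are scored m² = 1, the maximal
misfit; a degenerate *observed* configuration is an error.

Two permutation schemes are provided. `r0` re-places each host row's links
uniformly among symbionts, preserving row counts — the upstream package's
default, kept here as the API default for compatibility. Its nulls are
random *functions*, which for a one-to-one observed association are not
exchangeable with the observed permutation matrix: measured type-I error in
that regime was 0.11 at nominal 0.05. `full_shuffle` redraws all links
uniformly subject to the total-count and ≥1-link-per-host/per-symbiont
constraints (for a square one-to-one association these constraints force a
permutation matrix, which is drawn directly); its measured type-I error is
0.030–0.05, inside the exact binomial band, and it is the scheme used by the
calibration tests and the acceptance script. Users testing one-to-one
associations should prefer `full_shuffle`.

**Generalized RF.** Non-trivial splits (both sides ≥ 2 tips) are extracted
from each tree; every split pair is scored by the mutual information of the
two bipartitions (bits, from the 2 × 2 co-membership counts); a
maximum-weight bipartite matching (rectangular assignment) selects the split
pairing; the distance is 1 − 2·matched_info/(H₁ + H₂) with Hᵢ the summed
split entropies. Identical split sets give exactly 0 (values within 1e-12
of 0 are snapped). Among the information-based tree-distance family this is
the clustering-information variant; the choice is documented rather than
inherited, since published usage often does not pin the variant down.

**Multi-association.** When symbiont tips outnumber hosts, the RF
comparison is made well defined by seeded subsampling: per subsample, one
linked symbiont tip is chosen uniformly per host, the symbiont tree is
pruned to the chosen tips and relabeled by host, and the mean distance over
`n_subsamples` (default 100) is reported. A one-to-one association yields
exactly one subsample.

**Classification.** Signal: none if p ≥ α (0.05); else high if R² ≥ 0.20,
low otherwise. The 0.20 cut separates printed "Low" (R² = 0.11) from
"High" (R² = 0.20) calls in the survey this package re-implements and is
config-exposed because no source states it explicitly. Congruence: none
unless p < α and R² > 0.25; weak up to R² = 0.60, strong above; an optional
RF gate additionally requires RF ≤ gate. Threshold comparisons carry a 1e-9
guard so that values like 1 − 0.80 classify as 0.20.

## pan-GWAS

Per family, a two-sided Fisher's exact test (sum of tables with point
hypergeometric probability ≤ observed) of presence vs. the binary trait,
an odds ratio (a·d)/(b·c) with the Haldane +0.5 correction when any cell is
zero, and Bonferroni adjustment over the number of informative families
(families constant across the tested genomes are skipped and excluded from
the denominator). A hit passes at raw p < α (0.05) **and** Bonferroni
p ≤ the FWER cutoff (0.99). Clade filtering (e.g. testing pigmented and
nonpigmented clades separately) restricts the genome set before testing.
Phylogeny-aware pairwise-comparison corrections are deliberately not
implemented. Hits are ordered by ascending p, ties by family ID.

## Read-recruitment profiles

RPKM = reads / ((genome_length/10³) · (library_size/10⁶)); cells below the
detection threshold (default 0.1) are zeroed — thresholded values are
zeroed in place rather than excluding genomes, the simpler of the two
defensible readings. Bray-Curtis dissimilarity (two empty samples are at
distance 0 by convention, logged) feeds a hand-rolled UPGMA whose
tie-breaks are deterministic (smallest-member lexicographic pair), so
dendrograms are reproducible; merge heights are half the inter-cluster
distance and the output is ultrametric, with cophenetic distances equal to
the merge distances. Concordance with the host phylogeny is PACo between
host patristic distances and the dendrogram's cophenetic distances, with
samples linked to their host taxa; host tips without samples are dropped
with a warning. Mean-RPKM per sample group is a plain reporting helper.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes; all are pure functions of (config, seed).

*Cophylogeny.* Host trees are Yule (pure birth, rate 1) — the simplest
model matching the topology-only role host cladograms play here. The
symbiont process replays the host event sequence: at each bifurcation each
resident lineage is lost with `loss_prob`, otherwise codiverges into both
daughters; each daughter then independently host-switches with
`switch_prob` by *swapping* branches with a uniformly chosen other lineage
(lineages resident on the branch that is currently splitting are excluded
as partners). The swap formulation — two simultaneous prune-and-graft
moves — was chosen over single grafts because it conserves per-branch
symbiont occupancy, so every host tip remains occupied even at
switch_prob = 0.8, while still scrambling the host-relabeled topology
(mean generalized RF rises monotonically through 0 → 0.4 → 0.8). Single
uniform grafts in place of codivergence cannot keep all hosts occupied at
high switch rates at these sizes. Histories that still violate the
occupancy or minimum-size constraints (possible with loss) are resampled on
the fixed host tree. `multi_assoc_rate` adds Poisson extra root lineages.
Branch lengths accumulate host time.

*Pangenome.* Core families at prevalence 1; accessory families with
independent Bernoulli columns whose prevalence is Beta(1, 2) truncated to
(1/n, 0.95); Poisson(mean) genome-unique singletons; trait genes with
lifestyle-dependent presence probability at baseline 0.3 in the free-living
group and odds multiplied by `trait_odds_ratio` in the host-associated
group. All-zero realizations are redrawn so every family exists somewhere.

*ANI.* Block-diagonal similarity with symmetric Gaussian noise, clipped to
[0, 1], unit diagonal. *Reads.* One sample per host tip; Poisson counts
with mean depth × enrichment on linked genomes and depth elsewhere; genome
lengths uniform on [3, 6] Mbp; library sizes are 10× the mapped total
(floored at 1 so empty samples stay valid). `block_association` groups
hosts into contiguous clade blocks sharing a genome set — the regime in
which recruitment profiles mirror the host tree. A strictly one-genome-
per-host association gives near-unit Bray-Curtis between all samples and
hence no recoverable tree signal; the block construction is what the
concordance power analyses use.

What the simulations do **not** emulate: sequence evolution, rate
heterogeneity, biogeography, phylogenetically autocorrelated gene content
(accessory columns are exchangeable across genomes), compositional coupling
between the ANI blocks and the pangenome, or overdispersed (negative
binomial) read counts. Passing tests therefore demonstrate correctness of
the statistics and their operating characteristics under these idealized
conditions, not performance on real survey data.

## Problem sizes and verification

The analysis scripts and acceptance checks run at desk scale, chosen as the
smallest sizes at which the frequentist properties are measurable: 16-tip
host trees; 200 null replicates × 199 permutations for PACo type-I error;
100 replicates for power; 50 seeds per switching level for RF monotonicity;
100 genomes × 400 null families for the Fisher false-positive rate and
20 × 20 planted genes at odds ratio 8 for recovery; 50 simulations each for
profile-concordance power and null calibration. Procrustes m² is checked
against an explicit rotation-and-scale construction to 1e-8; generalized RF
against factorial enumeration of all split matchings on all 5- and 6-leaf
binary tree pairs; Fisher p against direct hypergeometric enumeration on
all tables with row margins ≤ 15; UPGMA against an independent
average-linkage implementation's cophenetic distances.

## Known limitations

- The survey-scale outputs of the study this package re-implements (its
  actual p/m²/RF values, 57 phylogroups, genus-level family counts,
  pan-GWAS odds ratios, per-family mean RPKMs) require its 236 genomes and
  single-worm metagenomes; only the printed-value arithmetic and the
  statistics' operating characteristics are reproducible here.
- `r0` permutation nulls are anticonservative for one-to-one associations
  (see above); the default is kept for upstream compatibility but
  `full_shuffle` is the calibrated choice.
- Heaps-fit openness is a decision rule, not an estimator; its γ threshold
  is arbitrary at the margin.
- UPGMA and the O(n²)–O(n³) matrix routines are written for hundreds of
  genomes/samples, not tens of thousands.
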