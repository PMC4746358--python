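# Methods

This note documents the models, estimators, numerical choices and
limitations of `photocoord`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model

The pipeline treats the photosynthesis panel as a fixed set of 78
transcripts in nine functional groups — C4 (5), Calvin (18), Cyt b6/f (5),
F-ATPase (7), PET (12), Lhca (5), Psa (9), Lhcb (5), Psb (12) — plus 30
cytosolic paralogs of the dark-reaction enzymes, observed as FPKM in 39
individuals at each of two sites (JH, QG). FPKM is interpreted as expression
level for nuclear transcripts and degradation level for chloroplast-encoded
transcripts (their steady state is degradation-controlled, and poly-A
selected RNA-seq captures the polyadenylated degradation intermediates).

## Candidate identification and merging

Hits are 12-column BLAST tabular records, strand-normalized on input
(reverse-strand target coordinates swapped, orientation kept on a flag).
Filtering keeps e-value ≤ 1e-60 and identity ≥ 85%. Coverage of a
query–target pair is the union of aligned query intervals divided by the
query length — the union (rather than the summed alignment lengths) keeps
coverage ≤ 1 when HSPs overlap; gap columns are not counted because the
intervals are query positions. Similarity is the unweighted mean identity
over the pair's hits. Best targets minimize e-value, with ties broken by
higher bit score, then lexicographic target id.

Split-transcript merging replaces manual alignment scrutiny with an explicit
rule: two queries sharing a best target merge when their aligned target
intervals overlap by less than 10% of the shorter union (near-identical
intervals are competing candidates, not fragments). Merge groups are
connected components of this disjointness graph; merged expression is the
per-sample arithmetic mean of the member FPKMs.

## Conserved blocks, distances, trees, classification

Block selection works per column: any column containing a gap or N is
non-retainable; otherwise a column is *flank* when its modal residue count
is ≥ 12, *conserved* when ≥ 8, else non-conserved. Runs of more than 4
contiguous non-conserved columns and all gap columns are dropped; each
remaining maximal run is trimmed so both ends are flank columns and kept if
at least 10 columns wide. This is a simplified, fully specified operator in
the spirit of the stringent Gblocks settings, not a bug-compatible clone of
Gblocks 0.91b. Note the flank threshold makes block selection impossible for
families with fewer than 12 sequences — the empty result is returned, and
the pipeline then uses the untrimmed alignment.

Distances are p-distances with pairwise deletion of gap/N columns (a pair
with no comparable site is an error); a Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) is available behind a flag. Neighbor joining is the
Saitou–Nei agglomeration on the Q criterion with deterministic tie-breaks
(smallest node-index pair in creation order). Negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving the
pair's summed length. On additive inputs the reconstruction is exact; the
tests verify the path metric equals the input to 1e-9 up to 7 taxa and
cross-check the topology against scikit-bio's NJ.

Bootstrap resamples alignment columns with replacement, rebuilds the NJ tree
per replicate, and scores each internal edge by the percentage of usable
replicates containing the same bipartition (replicates with an undefined
distance are skipped and counted). Classification assigns each unlabeled
leaf the class of the smallest bipartition side with support ≥ 50 that
contains the query and references of exactly one class; conflicts disqualify
a side, and a query with no qualifying side stays unclassified. A terminal
branch-length z-score within the family is reported as a descriptive
statistic for accelerated evolution ("remarkably long branch") but never
gates classification.

## Expression statistics

Per-transcript site medians use the standard even-count convention (mean of
the two middle values). "Up-regulated" means the QG median strictly exceeds
the JH median; exact equality is "unchanged" (ties have measure zero in
continuous FPKM but must be defined); two-fold means ratio ≥ 2 or ≤ 0.5.
When both medians are zero the ratio is undefined and flagged.

The KS test uses D = sup |ECDF_x − ECDF_y| and the asymptotic Kolmogorov
p-value at λ = (√ne + 0.12 + 0.11/√ne)·D with ne = nm/(n+m), for all sample
sizes (the study's set sizes are 23–32; small-sample exactness is out of
scope). The Wilcoxon rank-sum test computes U from summed average ranks;
with both sizes ≤ 10 and no ties the p-value is exact by full enumeration of
rank placements, otherwise a normal approximation with tie and continuity
corrections is used. The exact and approximate branches agree within 0.02
at sizes 9–10 (asserted in the tests).

## Clustering

Preprocessing follows the Cluster 3.0 chain in order: log2 (FPKM = 0 becomes
missing, mirroring that software's missing-data handling and avoiding −∞),
gene median-centering, gene normalization to unit sum of squares (zero rows
are left untouched), array median-centering, array normalization. Missing
cells are ignored by every step; rows or columns that end up entirely
missing are excluded and reported.

Clustering is agglomerative centroid linkage under correlation distance
1 − r (Pearson over shared non-missing positions; an uncentered variant is
available). A merged cluster is represented by the element-wise mean of its
*member* profiles — the true centroid, recomputed from members so missing
cells are weighted correctly. Pairs with fewer than two shared positions or
zero variance get the maximal distance 2 with a warning. Ties break to the
smallest node-index pair, making the procedure deterministic and
permutation-invariant up to relabeling.

Centroid linkage is not monotone: a later merge can sit lower than an
earlier one. Nothing downstream assumes sorted heights, and cutting into k
branches removes the k−1 *final* merges in agglomeration order — identical
to removing the k−1 highest merges whenever heights are monotone, but
guaranteed to produce exactly k branches when they are not. Site separation
is scored by cutting the sample tree at k = 2 and taking the better of the
two branch-to-site assignments (purity).

## Coordination

Spearman's ρ is the Pearson correlation of average ranks over the pooled 78
samples; constant transcripts have undefined ρ, recorded as missing and
excluded with a logged count. The background b is the median of |ρ| over all
distinct pairs (the signed median is reported alongside). Each group cell
counts member pairs with |ρ| strictly greater than b — ties count as not
exceeding — and is tested with the exact binomial tail P(X ≥ k), X ~
Bin(m, 1/2). The null rate 1/2 is justified by b being the empirical median
of the same coefficient population; because the m pairs in a cell are not
independent of each other or of b, the p-value is an approximation carried
over faithfully from the original procedure. No multiple-testing correction
is applied across the 45 cells, again matching the procedure being
reproduced.

The coordinated-set rule is this package's formalization of an outcome the
source analysis states without a rule: a group is coordinated when its
within-group p < α or at least one between-group p < α (α = 0.05,
configurable), and chloroplast transcripts outside coordinated groups are
added when they all fall in one gene-tree branch (tightly coordinated
degradation). The rule reproduces the six-units-plus-two-chloroplast outcome
on the published narrative. Its cost is multiplicity: with nine groups each
group effectively gets nine α-level tests, so under a global null the
per-group false-flag rate is roughly 1 − (1 − α′)^9 ≈ 25–30% (α′ slightly
below α because the binomial is discrete and the exceedance counts are
negatively dependent through b). The Monte-Carlo acceptance check reports
this rate honestly; a user who wants family-wise control should lower α or
restrict the rule to within-group cells.

Centrality is the mean |ρ| of a transcript to all others, a simple hub
score. The rendered relatedness table puts mean |ρ| (2 decimals, with
significance stars at p < 0.05/0.01/0.001, strict) in the upper triangle and
diagonal and binomial p (4 decimals) in the lower triangle, with group sizes
in the headers.

## Nucleotide diversity

π per transcript is computed from per-site allele counts as
Σ 2·p_j(1−p_j)·n_j/(n_j−1) over segregating sites, divided by the full
transcript length (monomorphic sites in the denominator; per-bp convention).
This is the standard SNP-frequency form of the Nei–Li average pairwise
difference, with the n/(n−1) unbiasedness factor; it equals the exhaustive
average over haplotype pairs exactly (asserted to 1e-12). Sites with fewer
than two sampled alleles are skipped with a warning; fixed differences
contribute nothing. Per-site sample sizes n_j are taken from the input table
as given. Site populations are compared by the KS test on per-transcript π.

## Synthetic data

The generator is the package's definition of the study conditions, not a
tuning dial.

* **Expression**: log2 FPKM for transcript i in sample s is
  base_i + shift_i·[site(s) = QG] + λ_i·f_g(i)(s) + ε, with one standard
  normal latent factor f_g per functional group per sample (shared across
  sites), ε ~ N(0, σ²), σ = 0.5 by default, and FPKM = 2^value (log-normal,
  matching the log2 preprocessing). 39 samples per site. Group shift means
  follow the reported regulation pattern — dark-reaction groups up
  (C4 +1.2, Calvin +1.0 log2 units, i.e. ~2-fold), PSII/PSI/F-ATPase/Lhcb
  down (−0.8 to −1.0), Lhca and PET mildly up (+0.4), paralogs near zero —
  with SD 0.4 across transcripts; mixed signs matter, because a uniform
  shift would be absorbed by array median-centering. The six coordinated
  units carry loading λ = 1, the remaining groups λ = 0.2, paralogs 0.
  Baseline log2 means put dark-reaction transcripts higher (≈9.5–10) than
  light and paralog transcripts (≈7–8), spanning the reported FPKM range.
* **Sequences**: Jukes–Cantor only — per branch of length d each site
  substitutes with probability (3/4)(1 − e^(−4d/3)), uniformly to another
  base. The closed form provides free oracles; the NJ stage needs nothing
  richer. No indels, so simulated alignments are gap-free.
* **SNP tables**: alternate-allele counts are drawn uniformly on 1..n−1 and
  sites accumulate until the summed per-site heterozygosity best matches
  target_π·length, so the estimator recovers the target up to one site's
  granularity. Demo diversity targets are uniform on 0.002–0.008 (centered
  on π ≈ 0.005, a realistic transcriptome-wide level for an outcrossing
  grass), identical in distribution at both sites.

What the generator does **not** emulate: count noise at low expression,
library-size variation, linkage between SNPs, indels and alignment error,
population structure within a site, and any dependence between expression
and sequence evolution. Passing tests therefore demonstrate that the
*procedures* recover planted structure at the study's dimensions, not that
the biological conclusions would replicate on new field data.

All generators, the pipeline, and the acceptance script are pure functions
of one seed, dispatched to named per-stage substreams by hashing
(`stage_seed`), each below 2^31.

## Problem sizes in tests and acceptance

Monte-Carlo checks use 100 seeds for coordination power/type-I (78
transcripts × 78 samples each), 10 seeds for site-separation purity, 50
seeds for π recovery and for the diversity type-I check, 20 seeds for
classification accuracy, and 15 random additive matrices per taxon count
(4–7) for NJ; the demo pipeline bootstraps 100–200 replicates. These sizes
give stable rates while keeping the whole suite and the acceptance script in
the tens of seconds.

## Known limitations

* The binomial coordination test is approximate (dependent pairs); its
  multiplicity inflation under the default rule is quantified above.
* The KS p-value is asymptotic; at set sizes around 5 it is conservative.
* Block selection is a specified simplification of Gblocks, not the program.
* The merge rule automates what was originally manual curation; its overlap
  tolerance (0.1) is a design constant, configurable per call.
* Bootstrap supports are computed on the distance/NJ pipeline only; no
  likelihood-based trees.
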