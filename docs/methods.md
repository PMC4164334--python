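# Methods

This note records what each stage computes, the operating-point defaults
and why they sit where they do, what the synthetic-data generator does
and does not emulate, and the numerical and policy choices that are not
obvious from the code.

## Binning model

Scaffolds are represented by canonical oligonucleotide frequency
profiles: for each k in {3, 4, 5, 6}, every window of k consecutive
bases is counted after merging each k-mer with its reverse complement
(so profiles are strand-invariant), each per-k block is normalized to
sum to one, and the blocks are concatenated. Windows containing a
non-ACGT character are skipped. Similarity between profiles is the
Pearson correlation r of the concatenated vectors; clustering uses
average linkage on the distance d = 1 − r.

A candidate bin is a flat cluster at d ≤ 0.10 (r ≥ 0.90) that contains
at least one scaffold carrying a diagnostic marker gene. Candidates then
pass two filters, both strict inequalities:

| parameter | default | rationale |
|---|---|---|
| first-pass scaffold length | > 3,000 bp | shorter scaffolds have noisy k-mer profiles |
| extraction correlation | r ≥ 0.90 | tight enough to separate genera by composition |
| cumulative bin size | > 1.9 Mbp | smallest plausible target genome |
| second-pass scaffold length | > 5,000 bp | read-support accounting on reliable scaffolds only |
| reads per bin | > 10,000 | enough cells for population-level inference |
| duplication ceiling | < 10% | above this a bin likely mixes two organisms |

Bins that exceed the duplication ceiling are split at the root of their
internal dendrogram into two sub-bins, recursively, until every piece is
below the ceiling or has fewer than two scaffolds; pieces that still
exceed it when the iteration budget runs out are flagged `unconverged`
rather than silently accepted.

## Quality model

A core genome is built from a table of gene-family occurrence counts
across reference genomes: a family is core when present in every
genome, its expected count is the minimum count across genomes, and the
conserved single-copy gene (CSCG) set is the families with exactly one
copy everywhere. For a bin:

* completeness = identified core occurrences / expected occurrences × 100,
  where per-family identification is capped at the expected count;
* duplication = CSCGs seen more than once / |CSCG| × 100;
* extrapolated genome size = total bp / (completeness/100) ×
  (1 − duplication/100), rounded to an integer. The capping convention
  is configurable because "identified" is ambiguous for families found
  above their expected count.

Refinement applies two scaffold-level rules before quality is reported:
a scaffold is removed when fewer than 60% of its genes' top taxonomy
hits support the target phylum (strictly below; scaffolds with no
annotated genes are retained and flagged instead of being judged on no
evidence), and a shorter scaffold is removed when ≥ 85% of its genes
have homologs on a single longer scaffold. Dedup processes scaffolds
longest-first (ties broken lexicographically by id), so "longer keeps"
is well defined.

## Variant model

Reads mapped to a scaffold are treated as independent single cells. Per
CDS, in order: (1) bases below Q30 whose call no other read supports at
that column revert to the column consensus (consensus ties break by
summed quality, then alphabetically); (2) SNPs are sites with ≥ 4×
coverage where ≥ 2 reads share a non-consensus allele; (3) only CDSs
with mean depth strictly above 7× are analyzed — one below the 8×
draft-genome convention, to admit more CDSs; (4) reads are grouped into
variant tracks.

Track grouping is single-link: two reads join when they overlap at
least one SNP site and agree at every SNP site they share. Two policy
choices are deliberate:

* **Parsimony for mutation-free reads.** A read carrying no alternate
  allele at any SNP site it covers is assigned to the consensus track
  and excluded from linking. Without this rule, such a read covering a
  single SNP site would bridge the reference group to a variant group
  through the shared consensus base and transitively merge incompatible
  haplotypes.
* **Conflicts void the CDS.** If transitive closure still chains reads
  that disagree at a shared SNP site, the CDS is classified
  `undetermined` rather than resolved arbitrarily.

The reference track has the most reads; ties break by identity to the
CDS consensus, then lexicographically, so the choice is deterministic.
dN/dS between a track and the reference is computed over their
codon-frame-aligned overlap with a counting estimator: per-codon
synonymous site fractions (changes to stop codons count as
nonsynonymous), pathway-averaged difference counts (pathways through
stops are excluded when an alternative exists), Jukes–Cantor correction
d = −3/4 ln(1 − 4p/3), bacterial codon table (NCBI table 11). dS > 2.0
is flagged as saturated. When dS = 0 the ratio is undefined; when dS is
saturated beyond the correction (pS ≥ 3/4) but dN is finite, the ratio
is reported as 0 (strong purifying signal) rather than undefined.

## Biogeography

Abundance is the percent of a sample's total reads (binned or not)
mapping to a bin's scaffolds, tabulated per site with winter/summer
pools and a TOTAL row. Scaffolds whose per-scaffold summer-read fraction
falls outside Tukey fences (k = 1.5) within their bin are flagged as
seasonal outliers and excluded from the abundance table; bins with fewer
than 4 scaffolds make no outlier calls. Seasonal differences use a
two-sided permutation t-test (pooled-variance t, default 10,000
shuffles, add-one p-value so p ≥ 1/(B+1)); shuffles are vectorized as
argsorts of uniform noise.

## Synthetic communities: what is and is not emulated

Each genome is drawn from its own order-2 Markov chain with an
independently sampled transition matrix — enough compositional signal
for k-mer binning without modelling a real organism. Genomes are chopped
into scaffolds (5–20 kb by default; a terminal fragment shorter than the
minimum is dropped). Reads are Sanger-like: normally distributed lengths
(mean 1,008 bp, sd 150, floor 100), substitution errors at 10⁻³, ~97%
of bases ≥ Q30, no indels, no chimeras, no cloning bias, no
chromatogram model. Per-sample read counts are exact; genome membership
per read follows a genome × sample expected-fraction matrix with an
implicit background genome absorbing the remainder. The default
community (4 genomes × 2.2 Mbp, six samples, 13,000 reads each) has one
summer bloomer, one winter-dominant genome and two intermediates; the
expected fractions are scaled up relative to realistic rare-biosphere
abundances so that bins clear the read-support filter at desk scale.

Planted structure: each genome carries one marker gene and a configured
number of single-copy core families (plus a few deliberate two-copy
families), which makes completeness/duplication exactly predictable.
Planted CDS haplotypes differ from haplotype 1 by exact counts of
synonymous and nonsynonymous single-nucleotide changes (at most one per
codon, never creating a stop), confined to the stretch of the CDS
covered by every tiled haplotype read so each read spans all of its
haplotype's SNP sites; the host CDS region is rewritten stop-free
before regular reads are drawn, so background reads agree with
haplotype 1. A separate codon-process simulator (`evolve_coding_pair`)
evolves sequence pairs at a chosen dN/dS for validating the estimator.

## Limitations

* The dN/dS estimator is a counting method; it has no codon-frequency
  or transition/transversion model and will be biased for strongly
  skewed mutation processes.
* Single-link track reconstruction cannot place reads that cover no SNP
  site of their haplotype; they fall to the consensus track by design.
* The taxonomy and homology inputs are abstracted as tables; gene
  calling, similarity search and family assignment are out of scope.
* Abundance treats reads as equal-weight cells; no length or copy-number
  normalization is attempted.
* The permutation test assumes exchangeability across samples; with only
  3 + 3 seasonal samples its resolution is limited to p ≥ 1/(B+1) and
  the t reference is degenerate for constant groups (handled explicitly).
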