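# Methods

This note documents the models and procedures `pavscape` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Absence calling from inaccessibility masks

The unit of analysis is the representative CDS of a protein-coding gene:
for multi-transcript genes the transcript with the longest summed CDS, with
transposable-element genes and genes whose CDS contains any non-ACGT base
excluded. All internal coordinates are 1-based inclusive (the GFF
convention); BED input is converted on read and overlapping or adjacent
mask intervals are merged.

An accession's *inaccessible regions* — intervals with no reliable base
calls, arising from large deletions or failed resequencing — are
intersected with the CDS exons (splice-aware: intronic bases never count).
A gene is called **absent** when the masked fraction of its CDS is
*strictly greater than 0.5*; exactly half masked is still present. The
choice of a strict inequality at the boundary is deliberate and tested.
Calling is monotone in the mask: adding intervals can only move a gene
toward absence.

Rows of the resulting P/A matrix are restricted to polymorphic genes:
genes absent nowhere are simply not P/A genes, and genes absent in *every*
accession go to a sidecar report. The latter class is structurally
unreliable in a single-reference design — reference-only genes and
systematically unmappable loci look identical — which is why it is
excluded from all downstream statistics.

## Rarefaction model

For a matrix with n accessions and per-gene absence counts m_g, the number
of distinct absent genes in a uniform sample of k accessions has exact
expectation Σ_g [1 − C(n−m_g, k)/C(n, k)] (the hypergeometric probability
that the sample misses all carriers, complemented and summed). The
Monte-Carlo sampler draws accession subsets without replacement and is
checked against this closed form and, for n ≤ 10, against full subset
enumeration. Confidence intervals are percentile (2.5/97.5) intervals
across replicates. The discovery curve y = a·ln(x) + b is fitted by OLS to
the *per-size replicate means* (the quantity a discovery plot shows), with
the natural logarithm; predictions round half away from zero. The
randomization p-value for an external observed count is two-sided and
mean-centered — the fraction of replicates at least as far from the
replicate mean, with an add-one correction so p is never exactly zero.

## Presence validation

The presence screen is a seed-and-extend local aligner: exact k-mer seeds
(word size 11), ungapped X-drop extension (match +1, mismatch −2, drop 12),
hits kept at identity ≥ 0.7, both query strands searched. Hit spans are
merged on the query and a candidate is *present* when merged coverage
strictly exceeds 0.5 of the query length — coverage is cumulative over
hits, not per best hit. An e-value threshold is intentionally not modeled:
e-values depend on database size, while the operative decision rule here is
length coverage. Presence is monotone in the coverage threshold, and every
reference gene validates against its own reference genome.

## Families and tandem clusters

Pairwise divergence is 1 − identity over the columns of a full-length
global alignment with affine gap costs (match +2, mismatch −1, open −5,
extend −0.5, free terminal gaps), terminal-gap columns excluded. Families
are single-linkage connected components over pairs with divergence
strictly below 0.3; everything else is a singleton. The all-vs-all
alignment is prefiltered by shared exact 12-mers (any shared 12-mer makes a
pair a candidate); at the divergences the generator plants (0.1 within
families, ~0.75 between unrelated genes) related pairs share hundreds of
12-mers, so the filter only removes alignments that could not produce an
edge, and a test compares filtered against exhaustive runs.

A cluster chains family co-members along a chromosome whenever each
*adjacent* pair (by gene rank) has at most 8 intervening genes — the
consecutive-neighbor reading of the cluster definition. An all-pairs
reading would forbid long tandem arrays, which are exactly the arrays the
clustering is meant to capture; the chain rule is verified against a
brute-force enumeration of maximal chains on small chromosomes.

## Diversity–frequency covariation

π of a locus is the average over unordered pairs of present alleles of
(mismatching comparable sites)/(comparable sites), with pairwise deletion
of sites where either allele carries an ambiguous base; fewer than two
present alleles give π = 0 by definition. Loci are sorted by absence count
with ties shuffled by a seeded RNG and cut into equal-size bins (remainder
to the last bin). The covariation summary is an OLS fit of bin-mean π (or
gene length) on (f, f²); r is defined as √R² of that fit and p comes from
the model F-test — the underlying analysis reports a "quadratic-like
correlation" without fixing the statistic, so this definition is declared
rather than inferred. A bin-free per-frequency mean table is exposed
alongside, without committing to any particular smoothing.

Desk-scale caveat: with few accessions, high-frequency loci keep only one
or two present alleles, where π is forced to 0 or rests on a single pair.
That degeneracy alone bends the high-frequency end downward. The null
calibration test therefore keeps ≥4 present alleles per locus; real-data
analyses at this cohort size should treat the top frequency classes' π with
the same suspicion.

## Trees

Both trees come from the same in-package Saitou–Nei neighbor joining:
iteratively join the pair minimizing Q(i,j) = (n−2)d(i,j) − R_i − R_j with
the standard branch-length formulas. Ties break toward the lowest index
pair of the working matrix, so output is deterministic; negative branch
lengths are clamped to zero with the deficit moved to the sister branch,
preserving the joined pair's path length. On additive matrices the
implementation reproduces the generating tree's topology and path lengths
to 1e-9 (tested for n ≤ 8), and its topology matches scikit-bio's
independent NJ on random matrices. The P/A tree uses binary p-distances
(fraction of loci with differing presence); the accession tree uses SNP
p-distances over concatenated present alleles of non-P/A genes with
pairwise deletion of ambiguous sites. Tree reconciliation and rendering
are out of scope; the programmatic surrogate is the Robinson–Foulds
distance between the two trees, computed on unrooted bipartitions.

## Chromosomal distribution

Chromosomes are cut into fixed windows (1 Mb default; smaller in
desk-scale runs so that tens of windows exist). A gene belongs to the
window containing its start coordinate. Per-window P/A proportion is
n_pa/n_total, *undefined* (not zero) for gene-free windows. Windows are
annotated with the distance from their midpoint to the nearest centromere
edge, and association is summarized by Spearman rank correlation per
chromosome and pooled — a full distance profile rather than a binary
near/far call, since "near the centromere" has no canonical cutoff.

## Enrichment statistics

All enrichment questions are 2×2 Pearson χ² tests on one degree of
freedom with **no** Yates continuity correction — the uncorrected statistic
is the one the published family-membership margins reproduce (χ² = 281
requires a non-P/A total of 24,597 = 27,004 − 2,407; the printed 24,570 is
treated as a typo). Categories may overlap, so category tests are
per-category against the complement, with Benjamini–Hochberg q-values
reported alongside raw p-values whenever more than one category is tested.

## ORF-disruption calling

Variants fully contained in a single CDS exon are applied right-to-left on
the plus-strand spliced sequence (a variant straddling an exon boundary has
no well-defined spliced effect and is ignored; overlapping variants are
rejected since no resolution rule is defined). A frameshift is a net
inserted-minus-deleted length ≢ 0 (mod 3); a premature stop is an in-frame
stop before the annotated final codon of the edited coding sequence; both
can co-occur. The caller is strand-aware (minus-strand genes are edited in
genome coordinates, then reverse-complemented before translation).

## Synthetic cohort generator

The generator is the package's study system. Defaults: 2 chromosomes × 2
Mb, 400 genes, 20 accessions, seed 0. It plants:

- **ORFs** built from sense codons (ATG … TAA, no internal stop), 100–400
  codons, split into two exons by a 60–200 bp intron; minus-strand genes
  store the reverse complement in the genome.
- **Families**: 30 families of 4 members mutated from a common seed ORF at
  per-member substitution rate 0.05 (≈0.1 pairwise divergence). 15 families
  are tandem-clustered (members at adjacent ranks); the rest are scattered
  with co-members ~half a chromosome apart, so no unplanned cluster exists.
- **A centromere** (middle 10% of each chromosome) with 10-fold reduced
  gene density via inverse-density placement of gene starts.
- **Deletions** from a geometric-decay absence spectrum over counts
  1..n−1 (absent-in-all is disallowed by construction, matching the
  filtered matrix). Deleted genes' full CDS is masked in the chosen
  accessions, so the caller sees masked fraction exactly 1.0 at deleted
  loci and 0 elsewhere — which is what makes exact truth-matrix recovery a
  fair test. Incidental (noise) masking is deliberately not simulated.
- **Diversity** per locus at absence frequency f following
  π(f) = c0 + c1·f + c2·f² (default peak 0.01 at f = 0.5): each planted
  site's derived base is carried by each present allele independently with
  probability 1/2, so a site contributes 0.5 expected pairwise mismatch and
  round(2·π·L) sites hit the target in expectation, independent of the
  number of present alleles. Non-P/A genes get a flat background π
  (default 0.004) so the accession tree has signal.
- **Disruptions** (10 premature stops, 10 frameshifts by default) in
  reserved plus-strand singleton genes that are never deleted: a single
  substitution turning an internal codon into a stop, or an anchored 1-bp
  deletion within one exon, each assigned to one accession's VCF. Truth
  records the planted *intent*; a frameshift may legitimately also create a
  downstream stop, so recovery asserts the frameshift flag rather than an
  exact "frameshift-only" status.
- **A functional category map**: one enriched category holding 40% of P/A
  genes but only 5% of non-P/A genes, the rest labeled basal.

Everything is a pure function of (config, seed); the same seed yields
byte-identical FASTA/GFF3/BED/VCF/TSV output.

What the generator does **not** emulate — and what passing recovery tests
therefore do not show about real data: read-mapping artifacts and partial
or spurious masking (real inaccessibility is noisy, so real calls carry a
false-positive rate the generator's exact masks cannot produce);
recombination and linkage (diversity is planted site-wise, not evolved);
insertions relative to the reference; transposons; segmental duplication
beyond the planted families; any correlation between families and deletion
status.

## Problem sizes and determinism

Tests run the default 400-gene/20-accession cohort once per session
(the all-vs-all family alignment dominates at ~30 s), use 2,000 replicates
for sampler-vs-expectation comparisons, 100 kb windows so that ~40 windows
carry the centromere profile, and 10 frequency bins for covariation on 200
P/A loci — sizes chosen so the whole suite completes in about a minute
while every statistical check retains power. Every random stage takes an
explicit seed; `run-all` derives per-stage seeds from one master seed, and
two runs with the same configuration produce identical summaries.

Known numerical choices worth restating: strict inequalities at the 0.5
absence fraction, the 0.3 divergence threshold and the 0.5 coverage
threshold; half-away-from-zero rounding in curve prediction; percentile
CIs; lexicographic NJ tie-breaking; zero-clamped NJ branch lengths;
pairwise deletion of ambiguous sites in all distance/diversity
computations.
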