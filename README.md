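# pavscape

**Gene presence/absence (P/A) landscape analysis for resequenced cohorts.**

When many individuals of a species are resequenced against one reference
genome, some reference genes are simply missing from some individuals:
*presence/absence polymorphisms*. `pavscape` is a tested, reusable pipeline
for calling those absent genes and characterizing the resulting P/A
landscape, built around the kind of data the *Arabidopsis thaliana*
resequencing projects produce — per-accession consensus genomes whose
"inaccessible regions" (large deletions or uncalled stretches) are the
footprint of gene loss.

## What it computes

Given a reference annotation (GFF3 + FASTA), per-accession inaccessibility
masks (BED) and optional variant calls (VCF):

- **Absence calling** — a gene is called absent in an accession when
  strictly more than half of its representative (longest) CDS lies in
  inaccessible regions; calls are assembled into a genes × accessions P/A
  matrix. Genes absent in *every* accession are reported separately, not
  kept: against a single reference they cannot be told apart from
  systematically unmappable loci.
- **Frequency spectrum and rarefaction** — the absent-allele frequency
  spectrum, and the expected number of distinct absent genes among *k*
  sampled accessions. The Monte-Carlo discovery curve has a closed-form
  companion by inclusion–exclusion,

  E[count] = Σ_g [ 1 − C(n−m_g, k) / C(n, k) ],

  where m_g is gene *g*'s absence count among *n* accessions. The curve is
  summarized by an OLS fit y = a·ln(x) + b, which predicts absent-gene
  counts at unsampled cohort sizes; a randomization test compares an
  externally observed count against the sampling distribution.
- **Presence validation** — an internal seed-and-extend local-alignment
  screen (exact k-mer seeds, ungapped X-drop extension, hits at ≥70%
  identity): a candidate is present in an assembled genome when merged hit
  spans cover >50% of its CDS.
- **Families and tandem clusters** — single-linkage families over pairs
  with global-alignment nucleotide divergence < 0.3 (≥70% identity);
  clusters chain family co-members with ≤8 intervening genes between
  neighbors.
- **Diversity–frequency covariation** — nucleotide diversity π (average
  pairwise mismatch fraction) of the present alleles per P/A locus;
  equal-size frequency bins (ties shuffled by a seeded RNG); quadratic OLS
  of bin-mean π (and gene length) on absence frequency f and f², with
  r = √R² and an F-test p-value.
- **Trees** — a P/A tree from binary p-distances between accession
  presence profiles and an accession tree from SNP p-distances over
  non-P/A genes, both via an in-package Saitou–Nei neighbor-joining
  implementation (deterministic tie-breaking, negative branches clamped),
  plus their Robinson–Foulds distance.
- **Chromosomal distribution** — per-window (default 1 Mb) P/A gene
  proportions and a centromere-distance profile with Spearman rank
  correlation.
- **Enrichment** — Pearson 2×2 χ² (no continuity correction) of P/A status
  against gene groupings and functional categories, with BH q-values.
- **ORF disruption** — frameshift (net indel length ≢ 0 mod 3) and
  premature-stop calls from applying an accession's variants to the CDS.

A fully truth-tabled **synthetic cohort generator** emulates all of this —
planted families and tandem arrays, a gene-poor centromere with
centromere-enriched deletions, a configurable absence spectrum, a quadratic
diversity law π(f), and planted disruptions — so every stage has an exact
recovery test.

## Worked example

Run the full pipeline on a small synthetic cohort (80 genes, 10 accessions,
35 planted P/A genes):

```bash
pavscape run-all --config config.yaml --out-dir out/
```

with `config.yaml`:

```yaml
seed: 5
cohort:
  n_genes: 80
  n_pa_genes: 35
  n_families: 6
  family_size: 4
  n_clustered_families: 3
  n_accessions: 10
  chromosome_length: 500000
  disruption_plan: [3, 3]
thresholds:
  reps: 2000
  n_bins: 7
  window_size: 100000
```

The summary it prints (and writes to `out/summary.json`) includes:

```
"n_reference_genes": 80,
"n_pa_genes": 35,
"mean_absent_per_accession": 9.2,
"mean_absent_proportion_pct": 11.5,
"fit_a": 11.47470159253157,
"fit_b": 7.932787299347652,
"mean_pi": 0.00604476045007723,
"r_pi": 0.9970737962631011,
"pct_pa_in_families": 31.4,
"pct_pa_clustered": 14.3,
"centromere_rho_pooled": -0.8952737857857513,
"rf_distance_pa_vs_accession_tree": 12
```

Reading this: all 35 planted P/A genes were recovered; an accession is
missing 9.2 genes on average (11.5% of the annotation — synthetic cohorts
are deliberately deletion-rich); the discovery curve grows as
y ≈ 11.5·ln(x) + 7.9; the planted quadratic diversity law shows up as
r = 0.997 across frequency bins; and the planted centromere enrichment
appears as a strongly negative rank correlation between a window's
centromere distance and its P/A proportion. `out/curve.tsv` puts the
Monte-Carlo means next to the exact inclusion–exclusion expectations
(k = 1: 9.10 vs 9.20; k = 5: 25.96 vs 25.95).

Each stage is also available separately (`pavscape call`, `rarefy`,
`families`, `covary`, `tree`, `chromdist`, `enrich`, `disrupt`,
`validate`, `simulate`) and as plain library functions.

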