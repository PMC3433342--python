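"""Synthetic cohort generator with full truth tables.

The generator emulates the statistical structure of a resequenced plant
cohort analyzed against a single reference: a multi-chromosome annotated
reference carrying gene families (some tandem-clustered, some scattered) and
a gene-poor centromere; per-accession inaccessibility masks encoding gene
deletions drawn from a configurable absent-allele frequency spectrum, by
default enriched near centromeres; present-allele sequences whose nucleotide
diversity follows a configurable quadratic law pi(f) of the absence
frequency; and ORF-disrupting variants (premature stops and frameshifts).

Every planted feature is recorded in :class:`TruthTables`, so each
downstream stage of the pipeline has an exact recovery target.  All output
is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import (
    AccessionGenome,
    GeneModel,
    Interval,
    Variant,
    revcomp,
    write_bed,
    write_genome_fasta,
    write_gff3,
    write_pa_matrix,
    write_vcf,
)
from .pa_calling import PAMatrix

__all__ = [
    "CohortConfig",
    "TruthTables",
    "SyntheticCohort",
    "default_spectrum",
    "generate_reference",
    "generate_accessions",
    "generate_cohort",
    "write_cohort",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


def default_spectrum(
    n_pa_genes: int, n_accessions: int, decay: float = 0.75
) -> Dict[int, int]:
    """Geometric-decay absent-allele spectrum over counts 1..n_accessions-1.

    Mimics the empirically observed shape: many genes absent in one or a few
    accessions, few absent in most.  Counts sum exactly to *n_pa_genes*.
    """
    ms = np.arange(1, n_accessions)
    weights = decay ** (ms - 1)
    raw = weights / weights.sum() * n_pa_genes
    counts = np.floor(raw).astype(int)
    counts[0] += n_pa_genes - counts.sum()  # remainder to the singleton class
    return {int(m): int(c) for m, c in zip(ms, counts) if c > 0}


@dataclass(frozen=True)
class CohortConfig:
    """Desk-scale defaults: 2 chromosomes x 2 Mb, 400 genes, 20 accessions.

    ``deletion_spectrum=None`` resolves to :func:`default_spectrum` with
    *n_pa_genes* P/A genes.  ``diversity_law`` holds (c0, c1, c2) of
    pi(f) = c0 + c1 f + c2 f^2 for present alleles of P/A loci at absence
    frequency f; the default peaks at pi = 0.01 at f = 0.5.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    n_genes: int = 400
    n_accessions: int = 20
    # family plan
    n_families: int = 30
    family_size: int = 4
    within_family_divergence: float = 0.1
    n_clustered_families: int = 15
    # centromere
    centromere_fraction: float = 0.10  # middle slice of each chromosome
    centromere_enrichment: bool = True
    centromere_gap_factor: float = 10.0  # intergenic gaps scale inside it
    # deletions
    n_pa_genes: int = 200
    deletion_spectrum: Optional[Dict[int, int]] = None
    # diversity
    diversity_law: Tuple[float, float, float] = (0.0, 0.04, -0.04)
    background_pi: float = 0.004
    # ORF disruptions (premature stops, frameshifts)
    disruption_plan: Tuple[int, int] = (10, 10)
    # enriched functional category planting
    enriched_category: str = "defense"
    enriched_category_pa_fraction: float = 0.4
    enriched_category_background_fraction: float = 0.05
    # gene geometry
    min_codons: int = 100
    max_codons: int = 400
    seed: int = 0

    def resolved_spectrum(self) -> Dict[int, int]:
        spec = (
            dict(self.deletion_spectrum)
            if self.deletion_spectrum is not None
            else default_spectrum(self.n_pa_genes, self.n_accessions)
        )
        for m in spec:
            if not 1 <= m <= self.n_accessions - 1:
                raise ValueError(
                    f"spectrum count m={m} outside [1, {self.n_accessions - 1}] "
                    "(absent-in-all is disallowed)"
                )
        return spec

    def centromere(self, chrom_len: int) -> Interval:
        half = self.centromere_fraction / 2.0
        return (
            int(chrom_len * (0.5 - half)) + 1,
            int(chrom_len * (0.5 + half)),
        )

    def validate(self) -> None:
        spec = self.resolved_spectrum()
        n_pa = sum(spec.values())
        n_reserved = sum(self.disruption_plan)
        if n_pa + n_reserved > self.n_genes:
            raise ValueError("spectrum plus disruption reserve exceeds n_genes")
        if self.n_families * self.family_size + n_reserved > self.n_genes:
            raise ValueError("family plan plus disruption reserve exceeds n_genes")
        if self.n_clustered_families > self.n_families:
            raise ValueError("more clustered families than families")
        if self.family_size > 2 * self.n_chromosomes:
            raise ValueError(
                "scattered families need at most 2 members per chromosome; "
                "reduce family_size or add chromosomes"
            )
        c0, c1, c2 = self.diversity_law
        f = np.linspace(0.0, 1.0, 101)
        if np.any(c0 + c1 * f + c2 * f * f < -1e-12):
            raise ValueError("diversity law is negative somewhere on [0, 1]")


@dataclass
class TruthTables:
    """Ground truth for every planted feature of a synthetic cohort."""

    pa_matrix: PAMatrix
    spectrum: Dict[int, int]
    families: List[Tuple[str, ...]]  # sorted member tuples
    clusters: List[Tuple[str, Tuple[str, ...]]]  # (chromosome, ordered members)
    pi_targets: Dict[str, float]
    disruptions: List[Tuple[str, str, str]]  # (gene, accession, planted kind)
    centromeres: Dict[str, Interval]
    centromere_enriched: bool
    category_map: Dict[str, set] = field(default_factory=dict)
    enriched_category: str = ""


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genes: List[GeneModel]
    genome: Dict[str, str]
    accessions: List[AccessionGenome]
    alleles: Dict[str, Dict[str, str]]  # gene -> accession -> coding allele
    truth: TruthTables


# ---------------------------------------------------------------------------
# sequence helpers


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA: a clean ORF with no internal stop."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute a ``rate`` fraction of positions (distinct, random)."""
    n_mut = int(round(rate * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in _BASES if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


def _spliced_to_genomic(intervals: Sequence[Interval], offset: int) -> int:
    """Genomic coordinate of 0-based offset in the plus-strand spliced CDS."""
    for s, e in intervals:
        width = e - s + 1
        if offset < width:
            return s + offset
        offset -= width
    raise ValueError("offset beyond CDS")


def _same_exon(intervals: Sequence[Interval], pos1: int, pos2: int) -> bool:
    return any(s <= pos1 <= e and s <= pos2 <= e for s, e in intervals)


def _gene_starts(
    rng: np.random.Generator,
    chrom_len: int,
    centromere: Interval,
    n: int,
    factor: float,
) -> np.ndarray:
    """Sorted gene start coordinates with density 1/factor in the centromere.

    Uniform draws on a weighted axis (centromere shrunk by *factor*) are
    mapped back to physical coordinates, leaving a 2% tail margin free.
    """
    cs, ce = centromere
    cen_len = ce - cs + 1
    usable = int(chrom_len * 0.98)
    weighted_total = (usable - cen_len) + cen_len / factor
    u = np.sort(rng.random(n)) * weighted_total
    before = cs - 1  # weighted length preceding the centromere
    shrunk = cen_len / factor
    pos = np.where(
        u < before,
        u,
        np.where(
            u < before + shrunk,
            before + (u - before) * factor,
            u - shrunk + cen_len,
        ),
    )
    return pos.astype(int) + 1


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    config: CohortConfig,
) -> Tuple[List[GeneModel], Dict[str, str], dict]:
    """Annotated reference: genes with planted families/clusters, a genome,
    and placement metadata (family/cluster truth, disruption reserve).

    Deterministic given ``config.seed``.  Raises if the genes do not fit on
    their chromosomes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n_reserved = sum(config.disruption_plan)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]

    # --- roles ------------------------------------------------------------
    fam_members: List[List[str]] = []
    cursor = 0
    for _ in range(config.n_families):
        fam_members.append(gene_ids[cursor : cursor + config.family_size])
        cursor += config.family_size
    reserved = gene_ids[cursor : cursor + n_reserved]
    fillers = gene_ids[cursor + n_reserved :]
    clustered_fams = fam_members[: config.n_clustered_families]
    scattered_fams = fam_members[config.n_clustered_families :]

    # --- coding sequences (plus-strand spliced) ---------------------------
    plus_spliced: Dict[str, str] = {}
    for members in fam_members:
        n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
        seed_seq = _random_orf(rng, n_codons)
        for gid in members:
            plus_spliced[gid] = _mutate(
                rng, seed_seq, config.within_family_divergence / 2.0
            )
    for gid in reserved + fillers:
        n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
        plus_spliced[gid] = _random_orf(rng, n_codons)

    # --- gene order per chromosome ----------------------------------------
    # Clustered family members sit at adjacent ranks; scattered members are
    # split between the two halves of a chromosome (same family ordering in
    # both halves keeps co-members ~half a chromosome apart).
    n_chrom = config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    blocks_per_chrom: List[List[List[str]]] = [[] for _ in range(n_chrom)]
    for i, members in enumerate(clustered_fams):
        blocks_per_chrom[i % n_chrom].append(list(members))
    halves: List[List[List[str]]] = [[[], []] for _ in range(n_chrom)]  # chrom -> [h1, h2]
    for members in scattered_fams:
        for j, gid in enumerate(members):
            chrom_i = (j // 2) % n_chrom
            halves[chrom_i][j % 2].append(gid)
    loose = list(reserved) + list(fillers)
    rng.shuffle(loose)

    order_per_chrom: List[List[str]] = []
    per = [len(loose) // n_chrom] * n_chrom
    for i in range(len(loose) - sum(per)):
        per[i] += 1
    start = 0
    for ci in range(n_chrom):
        chunk = loose[start : start + per[ci]]
        start += per[ci]
        mid = len(chunk) // 2
        half_lists = []
        for hi, h_chunk in enumerate((chunk[:mid], chunk[mid:])):
            items: List[List[str]] = [[g] for g in h_chunk]
            if hi == 0:
                for block in blocks_per_chrom[ci]:
                    items.insert(int(rng.integers(0, len(items) + 1)), block)
            # scattered members at deterministic, evenly spaced slots
            specials = halves[ci][hi]
            if specials:
                step = max(1, len(items) // (len(specials) + 1))
                for si, gid in enumerate(specials):
                    items.insert(min((si + 1) * step, len(items)), [gid])
            half_lists.append([g for item in items for g in item])
        order_per_chrom.append(half_lists[0] + half_lists[1])

    # --- coordinates and genome -------------------------------------------
    # Gene starts are drawn by inverse-density sampling: uniform along the
    # chromosome arms, depressed by ``centromere_gap_factor`` inside the
    # centromere, so genes span the whole chromosome with a gene-poor middle.
    genes: List[GeneModel] = []
    genome: Dict[str, str] = {}
    centromeres: Dict[str, Interval] = {}
    for ci, chrom in enumerate(chrom_names):
        cen = config.centromere(config.chromosome_length)
        centromeres[chrom] = cen
        order = order_per_chrom[ci]
        starts = _gene_starts(
            rng, config.chromosome_length, cen, len(order),
            config.centromere_gap_factor,
        )
        segments: List[str] = []
        pos = 1  # next unwritten coordinate
        for gid, target_start in zip(order, starts):
            seq = plus_spliced[gid]  # coding (strand-oriented) sequence
            split = int(rng.integers(60, len(seq) - 60))
            intron = int(rng.integers(60, 201))
            g_start = max(int(target_start), pos + 50)  # resolve rare overlaps
            exon1 = (g_start, g_start + split - 1)
            exon2 = (exon1[1] + intron + 1, exon1[1] + intron + (len(seq) - split))
            if exon2[1] > config.chromosome_length:
                raise ValueError(
                    f"genes do not fit on {chrom}: need > {exon2[1]} bp"
                )
            strand = "+" if gid in reserved else ("+", "-")[int(rng.integers(2))]
            # the genome's plus strand carries revcomp(coding) for '-' genes
            genomic = seq if strand == "+" else revcomp(seq)
            segments.append(_random_dna(rng, g_start - pos))
            segments.append(genomic[:split])
            segments.append(_random_dna(rng, intron))
            segments.append(genomic[split:])
            genes.append(
                GeneModel(gid, chrom, strand, (exon1, exon2), seq)
            )
            pos = exon2[1] + 1
        segments.append(_random_dna(rng, config.chromosome_length - pos + 1))
        genome[chrom] = "".join(segments)
        assert len(genome[chrom]) == config.chromosome_length

    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    meta = {
        "families": [tuple(sorted(m)) for m in fam_members],
        "clusters": [
            (chrom_names[i % n_chrom], tuple(m))
            for i, m in enumerate(clustered_fams)
        ],
        "reserved": reserved,
        "centromeres": centromeres,
    }
    return genes, genome, meta


# ---------------------------------------------------------------------------
# accession generation


def _plant_sites(
    rng: np.random.Generator,
    ref: str,
    carriers: Sequence[str],
    pi_target: float,
) -> Dict[str, str]:
    """Allele sequences for *carriers* with expected pairwise diversity
    ~ *pi_target*: each planted site's derived base is carried independently
    with probability 1/2, so each site contributes ~0.5 mismatch probability
    per pair and ``n_sites = round(2 pi L)`` sites hit the target."""
    alleles = {acc: list(ref) for acc in carriers}
    if len(carriers) >= 2 and pi_target > 0:
        n_sites = int(round(2.0 * pi_target * len(ref)))
        positions = rng.choice(len(ref), size=min(n_sites, len(ref)), replace=False)
        for p in positions:
            derived = [b for b in _BASES if b != ref[p]][int(rng.integers(3))]
            for acc in carriers:
                if rng.random() < 0.5:
                    alleles[acc][p] = derived
    return {acc: "".join(s) for acc, s in alleles.items()}


def _stop_gain_variant(
    rng: np.random.Generator, gene: GeneModel
) -> Optional[Variant]:
    """A single substitution turning an internal codon into a stop.

    Only for plus-strand genes (the generator reserves those for planting).
    """
    seq = gene.cds_sequence
    n_codons = len(seq) // 3
    candidates = []
    for ci in range(2, n_codons - 2):
        codon = seq[3 * ci : 3 * ci + 3]
        for j in range(3):
            for b in _BASES:
                if b == codon[j]:
                    continue
                if codon[:j] + b + codon[j + 1 :] in _STOPS:
                    candidates.append((3 * ci + j, b))
    if not candidates:
        return None
    off, b = candidates[int(rng.integers(len(candidates)))]
    pos = _spliced_to_genomic(gene.cds_intervals, off)
    return Variant(gene.chromosome, pos, seq[off], b)


def _frameshift_variant(
    rng: np.random.Generator, gene: GeneModel
) -> Optional[Variant]:
    """A 1-bp anchored deletion inside one exon of a plus-strand gene."""
    seq = gene.cds_sequence
    for _ in range(50):
        off = int(rng.integers(10, len(seq) - 10))
        p1 = _spliced_to_genomic(gene.cds_intervals, off - 1)
        p2 = _spliced_to_genomic(gene.cds_intervals, off)
        if _same_exon(gene.cds_intervals, p1, p2):
            return Variant(gene.chromosome, p1, seq[off - 1 : off + 1], seq[off - 1])
    return None


def generate_accessions(
    genes: Sequence[GeneModel],
    meta: dict,
    config: CohortConfig,
) -> Tuple[List[AccessionGenome], Dict[str, Dict[str, str]], TruthTables]:
    """Masks, alleles, disrupting variants and truth tables for the cohort.

    For each gene scheduled for absence count m, m accessions are drawn
    uniformly and the gene's full CDS is masked in them, so the downstream
    caller sees inaccessible fraction exactly 1.0 at deleted loci and 0
    elsewhere.  SNPs among present alleles realize the diversity law; the
    disruption plan is planted in reserved intact genes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    spectrum = config.resolved_spectrum()
    acc_ids = [f"acc{i:02d}" for i in range(config.n_accessions)]
    accessions = [AccessionGenome(accession_id=a) for a in acc_ids]
    by_id = {g.gene_id: g for g in genes}
    reserved = set(meta["reserved"])
    centromeres = meta["centromeres"]

    # --- choose the P/A genes, optionally centromere-weighted -------------
    eligible = [g for g in genes if g.gene_id not in reserved]
    n_pa = sum(spectrum.values())
    if config.centromere_enrichment:
        scale = 0.15 * config.chromosome_length
        weights = []
        for g in eligible:
            cs, ce = centromeres[g.chromosome]
            dist = 0.0 if cs <= g.start <= ce else min(abs(g.start - cs), abs(g.start - ce))
            weights.append(1.0 + 9.0 * np.exp(-dist / scale))
        p = np.array(weights) / np.sum(weights)
    else:
        p = None
    chosen_idx = rng.choice(len(eligible), size=n_pa, replace=False, p=p)
    pa_genes = [eligible[i] for i in sorted(chosen_idx)]
    m_values = [m for m, c in sorted(spectrum.items()) for _ in range(c)]
    rng.shuffle(m_values)
    absence_of: Dict[str, List[int]] = {}
    for gene, m in zip(pa_genes, m_values):
        carriers = rng.choice(config.n_accessions, size=m, replace=False)
        absence_of[gene.gene_id] = sorted(int(i) for i in carriers)
        for ai in carriers:
            acc = accessions[int(ai)]
            acc.mask.setdefault(gene.chromosome, []).extend(gene.cds_intervals)
    for acc in accessions:
        acc.normalize()

    # --- truth P/A matrix (gene order = reference order) -------------------
    pa_ids = [g.gene_id for g in genes if g.gene_id in absence_of]
    presence = np.ones((len(pa_ids), config.n_accessions), dtype=bool)
    for gi, gid in enumerate(pa_ids):
        for ai in absence_of[gid]:
            presence[gi, ai] = False
    truth_matrix = PAMatrix(pa_ids, acc_ids, presence)

    # --- alleles with planted diversity ------------------------------------
    c0, c1, c2 = config.diversity_law
    alleles: Dict[str, Dict[str, str]] = {}
    pi_targets: Dict[str, float] = {}
    for g in genes:
        absent = set(absence_of.get(g.gene_id, ()))
        carriers = [a for i, a in enumerate(acc_ids) if i not in absent]
        if g.gene_id in absence_of:
            f = len(absent) / config.n_accessions
            pi_t = max(0.0, c0 + c1 * f + c2 * f * f)
        else:
            pi_t = config.background_pi
        pi_targets[g.gene_id] = pi_t
        alleles[g.gene_id] = _plant_sites(rng, g.cds_sequence, carriers, pi_t)

    # --- disruptions --------------------------------------------------------
    n_stop, n_fs = config.disruption_plan
    reserved_order = list(meta["reserved"])
    disruptions: List[Tuple[str, str, str]] = []
    for i, gid in enumerate(reserved_order[: n_stop + n_fs]):
        gene = by_id[gid]
        kind = "premature_stop" if i < n_stop else "frameshift"
        v = (
            _stop_gain_variant(rng, gene)
            if kind == "premature_stop"
            else _frameshift_variant(rng, gene)
        )
        if v is None:  # no plantable site in this ORF; practically unreachable
            raise RuntimeError(f"could not plant a {kind} variant in {gid}")
        ai = int(rng.integers(config.n_accessions))
        accessions[ai].variants.append(v)
        disruptions.append((gid, acc_ids[ai], kind))

    # --- planted enriched functional category -------------------------------
    category_map: Dict[str, set] = {g.gene_id: {"basal"} for g in genes}
    pa_set = set(pa_ids)
    non_pa = [g.gene_id for g in genes if g.gene_id not in pa_set]
    n_cat_pa = int(round(config.enriched_category_pa_fraction * len(pa_ids)))
    n_cat_bg = int(round(config.enriched_category_background_fraction * len(non_pa)))
    for gid in rng.choice(pa_ids, size=n_cat_pa, replace=False):
        category_map[str(gid)] = {config.enriched_category}
    for gid in rng.choice(non_pa, size=n_cat_bg, replace=False):
        category_map[str(gid)] = {config.enriched_category}

    truth = TruthTables(
        pa_matrix=truth_matrix,
        spectrum=spectrum,
        families=meta["families"],
        clusters=meta["clusters"],
        pi_targets=pi_targets,
        disruptions=disruptions,
        centromeres=centromeres,
        centromere_enriched=config.centromere_enrichment,
        category_map=category_map,
        enriched_category=config.enriched_category,
    )
    return accessions, alleles, truth


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Reference + accessions in one call; see the stage functions."""
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    genes, genome, meta = generate_reference(config)
    accessions, alleles, truth = generate_accessions(genes, meta, config)
    return SyntheticCohort(config, genes, genome, accessions, alleles, truth)


# ---------------------------------------------------------------------------
# emission


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Emit the cohort as standard files: reference FASTA + GFF3, per-accession
    BED masks and VCFs, per-gene allele FASTAs, category TSV and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(cohort.genome, out / "reference.fa")
    write_gff3(cohort.genes, out / "annotation.gff3")
    contigs = {c: len(s) for c, s in cohort.genome.items()}
    (out / "masks").mkdir(exist_ok=True)
    (out / "vcf").mkdir(exist_ok=True)
    for acc in cohort.accessions:
        write_bed(acc.mask, out / "masks" / f"{acc.accession_id}.bed")
        write_vcf(acc.variants, out / "vcf" / f"{acc.accession_id}.vcf", contigs)
    alleles_dir = out / "alleles"
    alleles_dir.mkdir(exist_ok=True)
    for gid, per_acc in cohort.alleles.items():
        with open(alleles_dir / f"{gid}.fa", "w") as fh:
            for acc, seq in sorted(per_acc.items()):
                fh.write(f">{acc}\n{seq}\n")
    with open(out / "categories.tsv", "w") as fh:
        for gid in sorted(cohort.truth.category_map):
            for cat in sorted(cohort.truth.category_map[gid]):
                fh.write(f"{gid}\t{cat}\n")
    with open(out / "centromeres.tsv", "w") as fh:
        for chrom, (s, e) in sorted(cohort.truth.centromeres.items()):
            fh.write(f"{chrom}\t{s}\t{e}\n")
    write_pa_matrix(cohort.truth.pa_matrix, out / "truth_pa_matrix.tsv")
    with open(out / "truth_families.tsv", "w") as fh:
        for i, members in enumerate(cohort.truth.families):
            fh.write(f"fam{i:04d}\t{','.join(members)}\n")
    with open(out / "truth_clusters.tsv", "w") as fh:
        for i, (chrom, members) in enumerate(cohort.truth.clusters):
            fh.write(f"clu{i:04d}\t{chrom}\t{','.join(members)}\n")
    with open(out / "truth_disruptions.tsv", "w") as fh:
        for gid, acc, kind in cohort.truth.disruptions:
            fh.write(f"{gid}\t{acc}\t{kind}\n")
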