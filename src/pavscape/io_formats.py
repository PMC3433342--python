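"""Readers and writers for the standard formats the pipeline touches.

Every downstream module consumes only the domain types produced here:
:class:`GeneModel` (a reference protein-coding gene), :class:`AccessionGenome`
(one cohort member's consensus, inaccessibility mask and variants) and
:class:`Variant` (a VCF-style substitution or indel).

Coordinate convention: all internal coordinates are 1-based inclusive, the
GFF convention.  BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

Interval = Tuple[int, int]

__all__ = [
    "GeneModel",
    "AccessionGenome",
    "Variant",
    "read_annotation",
    "filter_gene_models",
    "read_genome",
    "read_mask",
    "merge_intervals",
    "read_variants",
    "read_pa_matrix",
    "write_pa_matrix",
    "write_newick",
    "read_newick",
    "write_genome_fasta",
    "write_gff3",
    "write_bed",
    "write_vcf",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware via Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """A reference gene reduced to its representative (longest) CDS.

    ``cds_intervals`` are 1-based inclusive genomic intervals sorted by start;
    ``cds_sequence`` is the spliced, strand-oriented (coding) sequence, so for
    a minus-strand gene it is the reverse complement of the concatenated
    plus-strand exon slices.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: Tuple[Interval, ...]
    cds_sequence: str
    is_te: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ivs = tuple(self.cds_intervals)
        if not ivs:
            raise ValueError(f"{self.gene_id}: no CDS intervals")
        for s, e in ivs:
            if e < s:
                raise ValueError(f"{self.gene_id}: interval ({s},{e}) has end < start")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
        object.__setattr__(self, "cds_intervals", ivs)
        span = sum(e - s + 1 for s, e in ivs)
        if span != len(self.cds_sequence):
            raise ValueError(
                f"{self.gene_id}: CDS sequence length {len(self.cds_sequence)} "
                f"!= interval total {span}"
            )
        if span < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the CDS."""
        return self.cds_intervals[0][0]

    @property
    def end(self) -> int:
        return self.cds_intervals[-1][1]

    @property
    def length(self) -> int:
        """Spliced CDS length in bp."""
        return len(self.cds_sequence)

    @property
    def plus_strand_spliced(self) -> str:
        """Spliced CDS in plus-strand orientation (coding seq for '+' genes)."""
        return self.cds_sequence if self.strand == "+" else revcomp(self.cds_sequence)


@dataclass(frozen=True)
class Variant:
    """One VCF-style variant: plus-strand ``ref``/``alt`` anchored at ``position``."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("variant position must be 1-based positive")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def end(self) -> int:
        """Last reference base touched (== position for SNPs)."""
        return self.position + len(self.ref_allele) - 1


@dataclass
class AccessionGenome:
    """One cohort member: consensus sequences, inaccessibility mask, variants.

    ``mask`` maps chromosome -> sorted, merged list of 1-based inclusive
    intervals with no reliable base calls (large deletions or uncalled bases).
    ``sequences`` may be empty when only the mask is needed (absence calling
    does not require the consensus itself).
    """

    accession_id: str
    sequences: Dict[str, str] = field(default_factory=dict)
    mask: Dict[str, List[Interval]] = field(default_factory=dict)
    variants: List[Variant] = field(default_factory=list)

    def normalize(self) -> "AccessionGenome":
        """Merge/sort mask intervals in place and sanity-check bounds."""
        for chrom, ivs in self.mask.items():
            merged = merge_intervals(ivs)
            if self.sequences.get(chrom):
                n = len(self.sequences[chrom])
                for s, e in merged:
                    if s < 1 or e > n:
                        raise ValueError(
                            f"{self.accession_id}: mask ({chrom},{s},{e}) outside "
                            f"chromosome of length {n}"
                        )
            self.mask[chrom] = merged
        return self


# ---------------------------------------------------------------------------
# annotation


def _transcript_cds(db, transcript) -> List[Interval]:
    return [(c.start, c.end) for c in db.children(transcript, featuretype="CDS")]


def _splice(chrom_seq: str, intervals: Sequence[Interval], strand: str) -> str:
    parts = [chrom_seq[s - 1 : e] for s, e in sorted(intervals)]
    seq = "".join(parts)
    return seq if strand == "+" else revcomp(seq)


def _looks_te(feature, te_keywords: Sequence[str]) -> bool:
    hay = [feature.featuretype]
    for values in feature.attributes.values():
        hay.extend(values)
    text = " ".join(hay).lower()
    return any(k.lower() in text for k in te_keywords)


def read_annotation(
    gff3_path,
    fasta_path,
    te_keywords: Sequence[str] = ("transposable_element",),
) -> List[GeneModel]:
    """Read a GFF3 + genome FASTA into representative :class:`GeneModel`s.

    Selection rules: for multi-transcript genes only the transcript with the
    longest summed CDS represents the gene; genes flagged as transposable
    elements (feature type or any attribute containing one of *te_keywords*)
    are excluded, as are genes whose CDS contains any base outside A/C/G/T.

    Raises ``ValueError`` for malformed GFF3 lines (with line number) and for
    CDS features on chromosomes missing from the FASTA.
    """
    with open(gff3_path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines, start=1):
        stripped = line.rstrip("\n")
        if not stripped or stripped.startswith("#"):
            continue
        if len(stripped.split("\t")) != 9:
            raise ValueError(f"malformed GFF3 line {i} in {gff3_path}: {stripped!r}")
    db = gffutils.create_db(
        "".join(lines),
        dbfn=":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genome = read_genome(fasta_path)

    models = []
    gene_types = [t for t in db.featuretypes() if t == "gene" or t.endswith("_gene")]
    for gtype in gene_types:
        for gene in db.features_of_type(gtype, order_by=("seqid", "start")):
            transcripts = list(db.children(gene, level=1))
            transcripts = [t for t in transcripts if t.featuretype in ("mRNA", "transcript")]
            candidates = []
            if transcripts:
                for t in transcripts:
                    ivs = _transcript_cds(db, t)
                    if ivs:
                        candidates.append((sum(e - s + 1 for s, e in ivs), t.id, ivs))
            else:  # CDS attached directly to the gene record
                ivs = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
                if ivs:
                    candidates.append((sum(e - s + 1 for s, e in ivs), gene.id, ivs))
            if not candidates:
                continue  # non-coding
            candidates.sort(key=lambda c: (-c[0], c[1]))
            _, _, intervals = candidates[0]
            intervals = sorted(intervals)
            if gene.seqid not in genome:
                raise ValueError(
                    f"gene {gene.id}: CDS references unknown chromosome {gene.seqid!r}"
                )
            strand = gene.strand if gene.strand in ("+", "-") else "+"
            seq = _splice(genome[gene.seqid], intervals, strand)
            if len(seq) < 3:
                continue
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chromosome=gene.seqid,
                    strand=strand,
                    cds_intervals=tuple(intervals),
                    cds_sequence=seq.upper(),
                    is_te=_looks_te(gene, te_keywords),
                )
            )
    models.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return filter_gene_models(models)


def filter_gene_models(genes: Iterable[GeneModel]) -> List[GeneModel]:
    """Drop TE genes and genes with ambiguous (non-ACGT) CDS bases.

    Idempotent: applying it to its own output changes nothing.
    """
    out = []
    for g in genes:
        if g.is_te:
            continue
        if set(g.cds_sequence.upper()) - set("ACGT"):
            continue
        out.append(g)
    return out


def read_genome(fasta_path) -> Dict[str, str]:
    """Chromosome -> uppercase sequence from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


# ---------------------------------------------------------------------------
# masks (BED)


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_mask(bed_path) -> Dict[str, List[Interval]]:
    """Read inaccessible regions from BED (0-based half-open) into merged
    1-based inclusive intervals keyed by chromosome."""
    raw: Dict[str, List[Interval]] = {}
    with open(bed_path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {i} in {bed_path}: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"BED line {i} in {bed_path}: end {end} <= start {start}"
                )
            raw.setdefault(chrom, []).append((start + 1, end))
    return {chrom: merge_intervals(ivs) for chrom, ivs in raw.items()}


# ---------------------------------------------------------------------------
# variants (VCF)


def read_variants(vcf_path) -> List[Variant]:
    """Read a (plain-text or bgzipped) VCF into :class:`Variant` records.

    Multi-allelic records are split into one Variant per ALT allele.
    """
    import pysam

    out: List[Variant] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
    return out


# ---------------------------------------------------------------------------
# P/A matrix TSV


def write_pa_matrix(matrix, tsv_path) -> None:
    """Write a presence/absence matrix as TSV: header row of accession ids,
    one row per gene, cells 1=present / 0=absent."""
    df = pd.DataFrame(
        matrix.presence.astype(int),
        index=list(matrix.gene_ids),
        columns=list(matrix.accession_ids),
    )
    df.to_csv(tsv_path, sep="\t", index_label="gene_id")


def read_pa_matrix(tsv_path):
    """Inverse of :func:`write_pa_matrix`; round-trip is the identity."""
    from .pa_calling import PAMatrix  # local import avoids a module cycle

    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {tsv_path}: {dupes}")
    values = df.to_numpy()
    bad = ~((values == 0) | (values == 1))
    if bad.any():
        raise ValueError(f"{tsv_path}: matrix cells must be 0 or 1")
    return PAMatrix(
        gene_ids=list(df.index.astype(str)),
        accession_ids=list(df.columns.astype(str)),
        presence=values.astype(bool),
    )


# ---------------------------------------------------------------------------
# trees (Newick)


def write_newick(tree, path) -> None:
    """Serialize a dendropy tree to Newick. Labels containing spaces are
    quoted; an unlabeled leaf is an error."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("cannot write Newick: tree contains an unlabeled leaf")
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick", preserve_spaces=True, suppress_rooting=True
            )
        )


def read_newick(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# emission helpers used by the synthetic-cohort generator and CLI


def write_genome_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    records = []
    from Bio.SeqRecord import SeqRecord

    for name, seq in sequences.items():
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Emit gene/mRNA/CDS features for a set of gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.is_te:
                attrs += ";biotype=transposable_element"
            fh.write(
                "\t".join(
                    [g.chromosome, "pavscape", "gene", str(g.start), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                "\t".join(
                    [g.chromosome, "pavscape", "mRNA", str(g.start), str(g.end),
                     ".", g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for j, (s, e) in enumerate(g.cds_intervals, start=1):
                fh.write(
                    "\t".join(
                        [g.chromosome, "pavscape", "CDS", str(s), str(e),
                         ".", g.strand, "0",
                         f"ID={mrna}.cds{j};Parent={mrna}"]
                    )
                    + "\n"
                )


def write_bed(mask: Mapping[str, Sequence[Interval]], path) -> None:
    """1-based inclusive intervals -> BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(mask):
            for s, e in sorted(mask[chrom]):
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def write_vcf(variants: Sequence[Variant], path, contigs: Mapping[str, int]) -> None:
    """Minimal VCF 4.2 emission (readable back with pysam)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for name, length in contigs.items():
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for v in sorted(variants, key=lambda v: (v.chromosome, v.position)):
        buf.write(
            f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
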