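"""Presence/absence calling from inaccessibility masks.

A gene is called *absent* in an accession when more than half of its
representative CDS lies inside that accession's inaccessible regions
(large deletions or stretches with no reliable base calls).  The calls are
assembled into a genes x accessions presence/absence matrix; genes absent in
every accession are unreliable by construction (the cohort was resequenced
against the reference, so reference-only genes cannot be distinguished from
systematically unmappable loci) and are reported separately rather than kept
in the matrix.

This module also hosts the pseudogenization caller: given an accession's
variants it decides whether a gene's ORF is disrupted by a frameshifting
indel and/or a premature stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .io_formats import AccessionGenome, GeneModel, Interval, Variant, merge_intervals

__all__ = [
    "PAMatrix",
    "DisruptionCall",
    "inaccessible_fraction",
    "call_absent",
    "build_pa_matrix",
    "absence_spectrum",
    "per_accession_summary",
    "false_call_rate",
    "call_disruption",
]

ABSENCE_FRACTION = 0.5  # strictly greater than half of the CDS must be masked


@dataclass
class PAMatrix:
    """Genes x accessions presence grid (True = present).

    After :func:`build_pa_matrix` filtering, every row satisfies
    ``1 <= absence_count <= n_accessions - 1``: genes absent nowhere are not
    P/A genes and genes absent everywhere are discarded.
    """

    gene_ids: List[str]
    accession_ids: List[str]
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.gene_ids), len(self.accession_ids)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.accession_ids)} accessions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def absence(self) -> np.ndarray:
        """Boolean absence grid (logical NOT of presence)."""
        return ~self.presence

    @property
    def absence_counts(self) -> np.ndarray:
        """Per-gene number of accessions in which the gene is absent."""
        return self.absence.sum(axis=1)

    def absence_count(self, gene_id: str) -> int:
        return int(self.absence_counts[self.gene_ids.index(gene_id)])


@dataclass(frozen=True)
class DisruptionCall:
    """ORF-disruption status of one gene in one accession.

    ``frameshift`` means the net inserted-minus-deleted base count inside the
    CDS is not a multiple of three; ``premature_stop`` means translation of
    the variant-applied CDS hits a stop before the annotated final codon.
    """

    gene_id: str
    accession_id: str
    frameshift: bool
    premature_stop: bool

    @property
    def status(self) -> str:
        if self.frameshift and self.premature_stop:
            return "both"
        if self.frameshift:
            return "frameshift"
        if self.premature_stop:
            return "premature_stop"
        return "intact"


# ---------------------------------------------------------------------------
# absence calling


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def inaccessible_fraction(
    gene: GeneModel, mask: Mapping[str, Sequence[Interval]]
) -> float:
    """Fraction of the spliced CDS covered by inaccessible intervals.

    Splice-aware: only bases inside the CDS exons count, not intronic bases
    of the genomic span.  A chromosome missing from the mask contributes no
    masked bases (fraction 0 for genes on it).
    """
    intervals = mask.get(gene.chromosome)
    if not intervals:
        return 0.0
    covered = 0
    for exon in gene.cds_intervals:
        for m in intervals:
            if m[0] > exon[1]:
                break
            covered += _overlap(exon, m)
    return covered / gene.length


def call_absent(gene: GeneModel, accession) -> bool:
    """True iff strictly more than half of the CDS is inaccessible.

    Exactly half masked is still called present (the rule is a strict
    inequality).  *accession* may be an :class:`AccessionGenome` or a bare
    mask mapping.
    """
    mask = accession.mask if isinstance(accession, AccessionGenome) else accession
    return inaccessible_fraction(gene, mask) > ABSENCE_FRACTION


def build_pa_matrix(
    genes: Sequence[GeneModel],
    accessions: Sequence[AccessionGenome],
    drop_all_absent: bool = True,
) -> Tuple[PAMatrix, List[str]]:
    """Call every gene in every accession and keep the polymorphic rows.

    Returns ``(matrix, discarded)`` where *matrix* holds genes absent in at
    least one (and, with *drop_all_absent*, not all) accessions, and
    *discarded* lists genes absent in every accession — the class the
    analysis treats as unreliable and reports in a sidecar file.
    """
    if len(accessions) < 2:
        raise ValueError("need at least 2 accessions")
    acc_ids = [a.accession_id for a in accessions]
    if len(set(acc_ids)) != len(acc_ids):
        raise ValueError("duplicate accession ids")
    n = len(accessions)
    gene_ids: List[str] = []
    rows: List[np.ndarray] = []
    discarded: List[str] = []
    for gene in genes:
        absent = np.array([call_absent(gene, acc) for acc in accessions])
        m = int(absent.sum())
        if m == 0:
            continue  # present everywhere: not a P/A gene
        if m == n and drop_all_absent:
            discarded.append(gene.gene_id)
            continue
        gene_ids.append(gene.gene_id)
        rows.append(~absent)
    presence = (
        np.array(rows, dtype=bool) if rows else np.zeros((0, n), dtype=bool)
    )
    return PAMatrix(gene_ids, acc_ids, presence), discarded


def absence_spectrum(matrix: PAMatrix) -> Dict[int, int]:
    """Absent-allele frequency spectrum: absence count -> number of genes.

    The counts always sum to the number of matrix rows.
    """
    values, counts = np.unique(matrix.absence_counts, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def per_accession_summary(matrix: PAMatrix, total_genes: int | None = None) -> dict:
    """Per-accession absent-gene counts with mean/min/max.

    When *total_genes* (the full reference gene count) is given, the mean
    absent fraction ``mean / total_genes`` is reported as
    ``mean_proportion_pct`` (in percent).
    """
    col = matrix.absence.sum(axis=0)
    out = {
        "per_accession": dict(zip(matrix.accession_ids, (int(c) for c in col))),
        "mean": float(col.mean()),
        "min": int(col.min()),
        "max": int(col.max()),
    }
    if total_genes:
        out["mean_proportion_pct"] = round(100.0 * out["mean"] / total_genes, 2)
    return out


def false_call_rate(n_false: int, n_tested: int, n_uncertain: int) -> float:
    """False-call rate of a genotyping check, excluding uncertain assays.

    ``n_false / (n_tested - n_uncertain)`` — e.g. 11 falsely-called genes out
    of 53 assayed with 9 uncertain gives 0.25.
    """
    informative = n_tested - n_uncertain
    if informative <= 0:
        raise ValueError("no informative assays")
    return n_false / informative


# ---------------------------------------------------------------------------
# ORF disruption (pseudogenization) calling


def _genomic_to_spliced(gene: GeneModel, pos: int) -> int:
    """0-based offset of genomic *pos* in the plus-strand spliced CDS."""
    offset = 0
    for s, e in gene.cds_intervals:
        if s <= pos <= e:
            return offset + (pos - s)
        offset += e - s + 1
    raise ValueError(f"position {pos} not inside the CDS of {gene.gene_id}")


def _contained_in_one_exon(gene: GeneModel, v: Variant) -> bool:
    return any(s <= v.position and v.end <= e for s, e in gene.cds_intervals)


def call_disruption(
    gene: GeneModel,
    variants: Iterable[Variant],
    accession_id: str = "",
) -> DisruptionCall:
    """Classify a gene's ORF status after applying an accession's variants.

    Only variants fully contained within a single CDS exon of the gene are
    applied (a variant straddling an exon boundary has an undefined spliced
    effect and is ignored).  Variants are applied right to left so earlier
    coordinates stay valid; overlapping variants within the CDS are rejected.
    A ref-allele mismatch against the gene sequence is an error.
    """
    relevant = [
        v
        for v in variants
        if v.chromosome == gene.chromosome and _contained_in_one_exon(gene, v)
    ]
    if not relevant:
        return DisruptionCall(gene.gene_id, accession_id, False, False)
    relevant.sort(key=lambda v: v.position)
    for a, b in zip(relevant, relevant[1:]):
        if b.position <= a.end:
            raise ValueError(
                f"{gene.gene_id}: overlapping variants at {a.position} and {b.position}"
            )
    seq = gene.plus_strand_spliced
    net = 0
    for v in reversed(relevant):
        off = _genomic_to_spliced(gene, v.position)
        if seq[off : off + len(v.ref_allele)] != v.ref_allele.upper():
            raise ValueError(
                f"{gene.gene_id}: variant ref {v.ref_allele!r} at {v.position} does not "
                f"match gene sequence {seq[off:off + len(v.ref_allele)]!r}"
            )
        seq = seq[:off] + v.alt_allele.upper() + seq[off + len(v.ref_allele) :]
        net += len(v.alt_allele) - len(v.ref_allele)
    frameshift = net % 3 != 0
    coding = seq if gene.strand == "+" else str(Seq(seq).reverse_complement())
    n_codons = len(coding) // 3
    protein = str(Seq(coding[: 3 * n_codons]).translate())
    # the final codon is the annotated stop; any stop before it is premature
    premature = "*" in protein[:-1] if protein else False
    return DisruptionCall(gene.gene_id, accession_id, frameshift, premature)
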