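"""Gene families by sequence divergence and tandem clusters along chromosomes.

Two genes are homologs when their full-length global-alignment nucleotide
divergence is below 0.3 (i.e. >= 70% identity); single-linkage connected
components of the homolog graph form multi-copy families, everything else is
a singleton.  A cluster is a chain of family co-members on one chromosome in
which each adjacent pair is separated by at most ``max_gap`` intervening
genes — the consecutive-neighbor reading, which (unlike an all-pairs rule)
allows long tandem arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx
from Bio import Align

from .io_formats import GeneModel
from .pa_calling import PAMatrix

__all__ = [
    "GeneFamily",
    "GeneCluster",
    "pairwise_divergence",
    "build_families",
    "rank_genes",
    "detect_clusters",
    "cluster_stats",
]


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: Tuple[str, ...]  # >= 2 gene ids, sorted

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a family needs at least 2 members")


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: Tuple[str, ...]  # ordered along the chromosome, >= 2

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # do not charge for terminal gaps; they are excluded from the divergence
    aligner.end_gap_score = 0.0
    return aligner


def pairwise_divergence(seq1: str, seq2: str) -> float:
    """1 - identity over aligned columns, terminal gap columns excluded.

    Full-length global alignment with affine gap costs; symmetric by
    construction of the column count.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align an empty sequence")
    seq1, seq2 = seq1.upper(), seq2.upper()
    if seq1 == seq2:
        return 0.0
    alignment = _aligner().align(seq1, seq2)[0]
    a, b = str(alignment[0]), str(alignment[1])
    # trim columns where either row has a terminal gap
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns == 0:
        return 1.0
    identical = sum(1 for i in range(start, end) if a[i] == b[i] and a[i] != "-")
    return 1.0 - identical / columns


def _kmer_candidate_pairs(
    seqs: Mapping[str, str], k: int, min_shared: int
) -> List[Tuple[str, str]]:
    """Pairs of ids sharing at least *min_shared* exact k-mers.

    Inverted-index prefilter for the all-vs-all alignment; sequences shorter
    than k are paired with everything (no evidence either way).
    """
    index: Dict[str, List[str]] = {}
    short = [g for g, s in seqs.items() if len(s) < k]
    for gid, seq in seqs.items():
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            index.setdefault(kmer, []).append(gid)
    shared: Dict[Tuple[str, str], int] = {}
    for ids in index.values():
        if len(ids) < 2:
            continue
        for a, b in combinations(sorted(ids), 2):
            shared[(a, b)] = shared.get((a, b), 0) + 1
    pairs = [p for p, c in shared.items() if c >= min_shared]
    for s in short:
        pairs.extend(tuple(sorted((s, g))) for g in seqs if g != s)
    return sorted(set(pairs))


def build_families(
    genes: Sequence[GeneModel] | Mapping[str, str],
    max_divergence: float = 0.3,
    prefilter_k: int = 12,
    min_shared_kmers: int = 1,
) -> Tuple[List[GeneFamily], List[str]]:
    """Single-linkage families over pairs with divergence strictly < threshold.

    *genes* may be GeneModels or a mapping gene_id -> CDS sequence.  Returns
    ``(families, singletons)``; together they partition the input.  The
    k-mer prefilter (any shared exact 12-mer by default) only skips
    alignments of unrelated sequence pairs; set ``prefilter_k=0`` to disable
    it and align every pair.
    """
    if not isinstance(genes, Mapping):
        seqs = {g.gene_id: g.cds_sequence for g in genes}
    else:
        seqs = dict(genes)
    if not seqs:
        raise ValueError("no genes")
    if prefilter_k:
        pairs = _kmer_candidate_pairs(seqs, prefilter_k, min_shared_kmers)
    else:
        pairs = list(combinations(sorted(seqs), 2))
    graph = nx.Graph()
    graph.add_nodes_from(seqs)
    for a, b in pairs:
        if pairwise_divergence(seqs[a], seqs[b]) < max_divergence:
            graph.add_edge(a, b)
    families: List[GeneFamily] = []
    singletons: List[str] = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components):
        if len(comp) >= 2:
            families.append(GeneFamily(f"fam{len(families):04d}", tuple(sorted(comp))))
        else:
            singletons.extend(comp)
    return families, sorted(singletons)


def rank_genes(genes: Iterable[GeneModel]) -> Dict[str, Tuple[str, int]]:
    """gene_id -> (chromosome, rank along chromosome by start coordinate)."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    order: Dict[str, Tuple[str, int]] = {}
    for chrom, members in by_chrom.items():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(members):
            order[g.gene_id] = (chrom, rank)
    return order


def detect_clusters(
    families: Sequence[GeneFamily],
    gene_order: Mapping[str, Tuple[str, int]],
    max_gap: int = 8,
) -> List[GeneCluster]:
    """Maximal chains of family co-members with <= *max_gap* intervening genes.

    Within each family and chromosome, members sorted by rank are chained
    whenever consecutive ranks differ by at most ``max_gap + 1``; maximal
    chains of size >= 2 become clusters.
    """
    clusters: List[GeneCluster] = []
    for fam in families:
        by_chrom: Dict[str, List[Tuple[int, str]]] = {}
        for gid in fam.members:
            if gid not in gene_order:
                raise ValueError(f"gene {gid} missing from the gene-order index")
            chrom, rank = gene_order[gid]
            by_chrom.setdefault(chrom, []).append((rank, gid))
        for chrom, ranked in sorted(by_chrom.items()):
            ranked.sort()
            chain = [ranked[0]]
            for prev, cur in zip(ranked, ranked[1:]):
                if cur[0] - prev[0] <= max_gap + 1:
                    chain.append(cur)
                else:
                    if len(chain) >= 2:
                        clusters.append(_mk_cluster(len(clusters), chrom, chain))
                    chain = [cur]
            if len(chain) >= 2:
                clusters.append(_mk_cluster(len(clusters), chrom, chain))
    return clusters


def _mk_cluster(i: int, chrom: str, chain: List[Tuple[int, str]]) -> GeneCluster:
    return GeneCluster(f"clu{i:04d}", chrom, tuple(gid for _, gid in chain))


def cluster_stats(
    pa_matrix: PAMatrix,
    families: Sequence[GeneFamily],
    clusters: Sequence[GeneCluster],
    all_gene_ids: Sequence[str],
) -> dict:
    """Counts and proportions of P/A genes in families and clusters.

    Percentages are reported to one decimal place, matching the reporting
    convention of the underlying analysis (e.g. 746 clustered of 2,407 P/A
    genes -> 31.0%).
    """
    pa = set(pa_matrix.gene_ids)
    family_members = {gid for fam in families for gid in fam.members}
    clustered = {gid for clu in clusters for gid in clu.members}
    n_pa = len(pa)
    stats = {
        "n_pa_genes": n_pa,
        "n_all_genes": len(set(all_gene_ids)),
        "n_families": len(families),
        "n_clusters": len(clusters),
        "pa_in_families": len(pa & family_members),
        "pa_singletons": len(pa - family_members),
        "pa_clustered": len(pa & clustered),
        "all_in_families": len(family_members),
        "all_clustered": len(clustered),
    }
    def pct(num, den):
        return round(100.0 * num / den, 1) if den else 0.0

    stats["pct_pa_in_families"] = pct(stats["pa_in_families"], n_pa)
    stats["pct_pa_singletons"] = pct(stats["pa_singletons"], n_pa)
    stats["pct_pa_clustered"] = pct(stats["pa_clustered"], n_pa)
    stats["pct_clustered_among_family_pa"] = pct(
        stats["pa_clustered"], stats["pa_in_families"]
    )
    stats["pct_all_clustered"] = pct(stats["all_clustered"], stats["n_all_genes"])
    return stats
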