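"""Distance matrices and neighbor-joining trees.

The accession relationships are summarized two ways: a P/A tree from the
p-distance between binary presence profiles (fraction of P/A loci at which
two accessions differ), and an accession tree from the SNP p-distance over
concatenated present alleles of non-P/A genes.  Both feed the same classic
Saitou-Nei neighbor-joining implementation: iteratively join the pair
minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j, with the standard branch-length
formulas, lexicographic tie-breaking, and negative branch lengths clamped to
zero (the deficit moved to the sister branch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Sequence

import dendropy
import numpy as np

from .pa_calling import PAMatrix

__all__ = [
    "DistanceMatrix",
    "binary_p_distance",
    "snp_p_distance",
    "neighbor_joining",
    "robinson_foulds",
    "tree_to_newick",
]

_ACGT = (ord("A"), ord("C"), ord("G"), ord("T"))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal and ordered labels."""

    labels: List[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance grid shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)


def binary_p_distance(matrix: PAMatrix) -> DistanceMatrix:
    """p-distance between accessions' binary presence profiles.

    d(i, j) = (# loci where presence differs) / (# loci).
    """
    if matrix.n_accessions < 3:
        raise ValueError("need at least 3 accessions for a tree")
    if matrix.n_genes == 0:
        raise ValueError("matrix has no loci")
    p = matrix.presence
    diff = (p[:, :, None] != p[:, None, :]).sum(axis=0)
    return DistanceMatrix(list(matrix.accession_ids), diff / matrix.n_genes)


def snp_p_distance(
    alignments: Mapping[str, Mapping[str, str]],
    accession_ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """SNP p-distance over concatenated per-gene allele alignments.

    *alignments* maps gene_id -> {accession_id -> aligned sequence}; every
    accession must be present in every gene.  d(i, j) = mismatching
    comparable sites / comparable sites, where a site is comparable for a
    pair when both bases are A/C/G/T.
    """
    if not alignments:
        raise ValueError("no alignments")
    if accession_ids is None:
        accession_ids = sorted(next(iter(alignments.values())))
    accession_ids = list(accession_ids)
    concat = {}
    for acc in accession_ids:
        parts = []
        for gid in sorted(alignments):
            if acc not in alignments[gid]:
                raise ValueError(f"accession {acc} missing from gene {gid}")
            parts.append(alignments[gid][acc].upper())
        concat[acc] = "".join(parts)
    arr = np.frombuffer(
        "".join(concat[a] for a in accession_ids).encode(), dtype=np.uint8
    ).reshape(len(accession_ids), -1)
    ok = np.isin(arr, _ACGT)
    n = len(accession_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            sites = int(comparable.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {accession_ids[i]} and {accession_ids[j]}"
                )
            mism = int((arr[i][comparable] != arr[j][comparable]).sum())
            d[i, j] = d[j, i] = mism / sites
    return DistanceMatrix(accession_ids, d)


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei NJ; returns an unrooted dendropy tree.

    Ties in the Q criterion break toward the lowest (i, j) index pair of the
    current working matrix, so identical input yields an identical tree.
    Negative branch lengths are clamped to 0 and the deficit is added to the
    sister branch, preserving the joined pair's path length.
    """
    if dist.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dist.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: List[dendropy.Node] = []
    for label in dist.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    d = dist.d.copy()

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin on the flattened row-major grid = lowest (i, j) on ties
        flat = int(np.argmin(q))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li  # move the deficit to the sister branch
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        new_d = np.zeros((n - 1, n - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # two nodes left: attach one under the other with the remaining distance
    a, b = nodes
    root = a if a.taxon is None else b if b.taxon is None else dendropy.Node()
    if root is a:
        root.add_child(b)
        b.edge.length = float(max(d[0, 1], 0.0))
    elif root is b:
        root.add_child(a)
        a.edge.length = float(max(d[0, 1], 0.0))
    else:  # both are leaves (n == 2 input cannot happen; defensive)
        root.add_child(a)
        root.add_child(b)
        a.edge.length = b.edge.length = float(max(d[0, 1], 0.0)) / 2.0
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def robinson_foulds(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds (symmetric bipartition) distance.

    The two trees are migrated onto a shared taxon namespace first; their
    leaf label sets must match.
    """
    tns = dendropy.TaxonNamespace()
    t1 = tree1.clone(depth=1)
    t2 = tree2.clone(depth=1)
    t1.migrate_taxon_namespace(tns)
    t2.migrate_taxon_namespace(tns)
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf label sets")
    for t in (t1, t2):  # compare as unrooted: a root bifurcation is not a split
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
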