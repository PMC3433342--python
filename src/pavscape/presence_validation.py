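"""Presence check of candidate P/A genes in independently assembled genomes.

A candidate gene is *present* in an assembly when local-alignment hits cover
more than half of its CDS.  The search is seed-and-extend: exact k-mer seeds
(default word size 11) are extended ungapped in both directions with an
X-drop rule; hits with identity >= ``min_identity`` contribute their query
spans, overlapping spans are merged, and the merged coverage is compared to
``min_coverage``.  Both strands of the query are searched.

This replaces a database BLASTN screen whose operative criterion is the
>50%-of-length coverage rule; an e-value cutoff is deliberately not modeled
(e-values depend on database size, the coverage rule does not).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .io_formats import AccessionGenome, GeneModel, merge_intervals, revcomp

__all__ = ["local_presence", "query_coverage", "validate_candidates", "validation_summary"]

logger = logging.getLogger(__name__)

_XDROP = 12.0
_MATCH = 1.0
_MISMATCH = -2.0


def _extend(query: str, target: str, qpos: int, tpos: int, k: int) -> Tuple[int, int, float]:
    """Ungapped X-drop extension of an exact k-mer seed.

    Returns (query start, query end exclusive, identity of the extended hit).
    """
    # left extension
    score = best = 0.0
    qi, ti = qpos - 1, tpos - 1
    best_qi = qpos
    while qi >= 0 and ti >= 0:
        score += _MATCH if query[qi] == target[ti] else _MISMATCH
        if score > best:
            best, best_qi = score, qi
        if best - score > _XDROP:
            break
        qi -= 1
        ti -= 1
    left = best_qi
    # right extension
    score = best = 0.0
    qi, ti = qpos + k, tpos + k
    best_qi = qpos + k
    while qi < len(query) and ti < len(target):
        score += _MATCH if query[qi] == target[ti] else _MISMATCH
        if score > best:
            best, best_qi = score, qi + 1
        if best - score > _XDROP:
            break
        qi += 1
        ti += 1
    right = best_qi
    span_q = query[left:right]
    span_t = target[tpos - (qpos - left) : tpos - (qpos - left) + (right - left)]
    matches = sum(1 for a, b in zip(span_q, span_t) if a == b)
    identity = matches / (right - left) if right > left else 0.0
    return left, right, identity


def _hit_spans(query: str, target: str, k: int, min_identity: float) -> List[Tuple[int, int]]:
    """Query spans of accepted ungapped hits of *query* against *target*."""
    qmers: Dict[str, List[int]] = {}
    for i in range(len(query) - k + 1):
        qmers.setdefault(query[i : i + k], []).append(i)
    spans: List[Tuple[int, int]] = []
    seen_diag_until: Dict[int, int] = {}  # diagonal -> query end already extended past
    for t in range(len(target) - k + 1):
        positions = qmers.get(target[t : t + k])
        if not positions:
            continue
        for q in positions:
            diag = t - q
            if seen_diag_until.get(diag, -1) >= q:
                continue  # this seed lies inside an already-extended hit
            left, right, identity = _extend(query, target, q, t, k)
            seen_diag_until[diag] = right
            if identity >= min_identity:
                spans.append((left, right))
    return spans


def query_coverage(
    query: str,
    target_sequences: Iterable[str],
    min_identity: float = 0.7,
    word_size: int = 11,
) -> float:
    """Fraction of the query covered by merged accepted hit spans (both strands)."""
    query = query.upper()
    covered: List[Tuple[int, int]] = []
    for target in target_sequences:
        target = target.upper()
        if not target:
            continue
        for q in (query, revcomp(query)):
            for left, right in _hit_spans(q, target, word_size, min_identity):
                if q is query:
                    covered.append((left + 1, right))  # 1-based inclusive
                else:  # map reverse-strand span back onto the forward query
                    covered.append((len(query) - right + 1, len(query) - left))
    if not covered:
        return 0.0
    merged = merge_intervals(covered)
    return sum(e - s + 1 for s, e in merged) / len(query)


def local_presence(
    query: str,
    target_genome: Mapping[str, str] | str,
    min_identity: float = 0.7,
    min_coverage: float = 0.5,
    word_size: int = 11,
) -> bool:
    """True iff accepted hit spans cover strictly more than *min_coverage*
    of the query length.  Empty target: False, with a logged warning."""
    if len(query) < 30:
        raise ValueError("query shorter than 30 bp")
    if isinstance(target_genome, str):
        targets: Sequence[str] = [target_genome]
    else:
        targets = list(target_genome.values())
    if not any(targets):
        logger.warning("presence check against an empty target genome")
        return False
    return query_coverage(query, targets, min_identity, word_size) > min_coverage


def validate_candidates(
    candidates: Sequence[GeneModel],
    reference_genomes: Sequence[AccessionGenome],
    min_identity: float = 0.7,
    min_coverage: float = 0.5,
    word_size: int = 11,
) -> pd.DataFrame:
    """Presence call of every candidate gene in every assembled genome.

    Returns a genes x genomes boolean DataFrame (True = present).
    """
    if not reference_genomes:
        raise ValueError("need at least one reference genome")
    rows = {}
    for gene in candidates:
        rows[gene.gene_id] = {
            g.accession_id: local_presence(
                gene.cds_sequence, g.sequences, min_identity, min_coverage, word_size
            )
            for g in reference_genomes
        }
    return pd.DataFrame.from_dict(rows, orient="index", dtype=bool)


def validation_summary(table: pd.DataFrame) -> dict:
    """Counts of genes with no match in any genome and matches in all."""
    if table.empty:
        return {"n_candidates": 0, "no_match_anywhere": 0, "present_everywhere": 0}
    return {
        "n_candidates": int(len(table)),
        "no_match_anywhere": int((~table).all(axis=1).sum()),
        "present_everywhere": int(table.all(axis=1).sum()),
    }
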