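"""Nucleotide diversity of present alleles and its covariation with
absent-allele frequency.

Per P/A locus, pi is the average pairwise proportion of differing comparable
sites among the alleles still present in the cohort (alignment columns where
either sequence has an ambiguous base are dropped for that pair).  Loci are
sorted by absence count — ties shuffled by a seeded RNG — and cut into
equal-size frequency bins; bin means of pi (or gene length) are regressed on
bin mean frequency and its square, giving the quadratic covariation summary
(r = sqrt(R^2) of the quadratic OLS fit, p from its F test).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .pa_calling import PAMatrix

__all__ = [
    "LocusDiversity",
    "BinSummary",
    "QuadraticFit",
    "nucleotide_diversity",
    "bin_by_frequency",
    "quadratic_covariation",
    "per_frequency_means",
    "covariation_report",
]

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class LocusDiversity:
    """One P/A locus: absence count, diversity of present alleles, CDS length."""

    gene_id: str
    absence_count: int
    pi: float
    length: int


@dataclass
class BinSummary:
    bin_index: int
    members: List[LocusDiversity]
    mean_frequency: float  # mean absence count / n_accessions
    mean_pi: float
    mean_length: float


@dataclass(frozen=True)
class QuadraticFit:
    beta0: float
    beta1: float
    beta2: float
    r: float
    p: float

    @property
    def vertex(self) -> float:
        """Stationary point -beta1 / (2 beta2) of the fitted parabola."""
        if self.beta2 == 0:
            raise ValueError("fit is linear; no vertex")
        return -self.beta1 / (2.0 * self.beta2)


def nucleotide_diversity(allele_sequences: Sequence[str]) -> float:
    """Average pairwise mismatch proportion over comparable sites.

    Sequences must be equal length (alleles reconstructed on the reference
    coordinate frame).  For each unordered pair, sites where either allele
    carries a non-ACGT base are excluded; a pair with no comparable sites
    contributes 0.  Fewer than two sequences give pi = 0.
    """
    seqs = list(allele_sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"allele sequences have unequal lengths: {sorted(lengths)}")
    if len(seqs) < 2:
        return 0.0
    arr = np.frombuffer("".join(s.upper() for s in seqs).encode(), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    ok = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    total = 0.0
    for i, j in combinations(range(len(seqs)), 2):
        comparable = ok[i] & ok[j]
        n = int(comparable.sum())
        if n:
            total += float((arr[i][comparable] != arr[j][comparable]).sum()) / n
    n_pairs = len(seqs) * (len(seqs) - 1) // 2
    return total / n_pairs


def bin_by_frequency(
    loci: Sequence[LocusDiversity],
    n_accessions: int,
    n_bins: int = 29,
    bin_size: int | None = None,
    seed: int = 0,
) -> List[BinSummary]:
    """Sort loci by absence count (ties shuffled with *seed*) into equal bins.

    With ``bin_size=None`` the size is ``len(loci) // n_bins``.  Consecutive
    blocks of *bin_size* loci form the bins; any remainder joins the last
    bin.  Deterministic given *seed*.
    """
    loci = list(loci)
    if len(loci) < n_bins:
        raise ValueError(f"{len(loci)} loci cannot fill {n_bins} bins")
    if bin_size is None:
        bin_size = len(loci) // n_bins
    if n_bins * bin_size > len(loci):
        raise ValueError("n_bins * bin_size exceeds the number of loci")
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(loci))
    order = sorted(range(len(loci)), key=lambda i: (loci[i].absence_count, tiebreak[i]))
    ordered = [loci[i] for i in order]
    bins: List[BinSummary] = []
    for b in range(n_bins):
        start = b * bin_size
        end = start + bin_size if b < n_bins - 1 else len(loci)
        members = ordered[start:end]
        bins.append(
            BinSummary(
                bin_index=b,
                members=members,
                mean_frequency=float(
                    np.mean([m.absence_count for m in members]) / n_accessions
                ),
                mean_pi=float(np.mean([m.pi for m in members])),
                mean_length=float(np.mean([m.length for m in members])),
            )
        )
    return bins


def quadratic_covariation(
    bins: Sequence[BinSummary], response: str = "pi"
) -> QuadraticFit:
    """OLS of bin-mean response on (f, f^2), f = bin mean absence frequency.

    Returns the coefficients, r = sqrt(R^2), and the p-value of the F test of
    the full quadratic model against the intercept-only model.
    """
    if len(bins) < 4:
        raise ValueError("need at least 4 bins")
    f = np.array([b.mean_frequency for b in bins])
    if response == "pi":
        y = np.array([b.mean_pi for b in bins])
    elif response == "length":
        y = np.array([b.mean_length for b in bins])
    else:
        raise ValueError("response must be 'pi' or 'length'")
    design = sm.add_constant(np.column_stack([f, f * f]))
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (degenerate bin frequencies)")
    if np.ptp(y) == 0:  # constant response: nothing to explain
        return QuadraticFit(float(y[0]), 0.0, 0.0, 0.0, 1.0)
    fit = sm.OLS(y, design).fit()
    r2 = max(0.0, float(fit.rsquared))
    p = float(fit.f_pvalue)
    if np.isnan(p):  # constant response: no variance to explain
        p = 1.0
    return QuadraticFit(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        beta2=float(fit.params[2]),
        r=float(np.sqrt(r2)),
        p=p,
    )


def per_frequency_means(
    loci: Sequence[LocusDiversity], n_accessions: int
) -> Dict[int, Tuple[float, float]]:
    """Bin-free summary: absence count -> (mean pi, mean length)."""
    groups: Dict[int, List[LocusDiversity]] = {}
    for loc in loci:
        groups.setdefault(loc.absence_count, []).append(loc)
    return {
        m: (
            float(np.mean([l.pi for l in grp])),
            float(np.mean([l.length for l in grp])),
        )
        for m, grp in sorted(groups.items())
    }


def covariation_report(
    matrix: PAMatrix,
    alleles: Mapping[str, Mapping[str, str]],
    lengths: Mapping[str, int],
    seed: int = 0,
    n_bins: int = 29,
    bin_size: int | None = None,
) -> dict:
    """Per-locus pi, frequency bins and both quadratic fits (pi and length).

    *alleles* maps gene_id -> {accession_id -> present-allele sequence};
    genes of the matrix missing from *alleles* are skipped.
    """
    counts = matrix.absence_counts
    loci: List[LocusDiversity] = []
    for i, gid in enumerate(matrix.gene_ids):
        if gid not in alleles:
            continue
        present = [
            alleles[gid][acc]
            for j, acc in enumerate(matrix.accession_ids)
            if matrix.presence[i, j] and acc in alleles[gid]
        ]
        pi = nucleotide_diversity(present) if present else 0.0
        loci.append(LocusDiversity(gid, int(counts[i]), pi, int(lengths[gid])))
    bins = bin_by_frequency(loci, matrix.n_accessions, n_bins, bin_size, seed)
    return {
        "loci": loci,
        "bins": bins,
        "fit_pi": quadratic_covariation(bins, "pi"),
        "fit_length": quadratic_covariation(bins, "length"),
        "mean_pi": float(np.mean([l.pi for l in loci])),
        "per_frequency": per_frequency_means(loci, matrix.n_accessions),
    }
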