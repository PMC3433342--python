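"""Enrichment statistics for P/A genes across gene groupings.

Every enrichment question here reduces to a 2x2 contingency table — rows:
in-category / not in-category, columns: P/A / non-P/A — tested with the
Pearson chi-square statistic on one degree of freedom, *without* Yates
continuity correction (the correction-free statistic is the one the margins
of the family analysis reproduce).  Functional categories come from an
external two-column TSV (gene_id, category); a gene may carry several
categories, so category tests are per-category against the complement, not
partition-wise, and Benjamini-Hochberg q-values accompany the raw p-values
whenever more than one category is tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pa_calling import PAMatrix

__all__ = [
    "ContingencyTable2x2",
    "chi_square_2x2",
    "category_report",
    "read_category_map",
    "frequency_class_share",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (a, b; c, d): rows in/out of category, columns P/A / non-P/A."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")

    @property
    def grid(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (statistic, df=1, p) with the p-value from the upper tail of
    chi-square with one degree of freedom.  A zero row or column margin is
    an error (an expected cell would be zero).
    """
    grid = table.grid
    if np.any(grid.sum(axis=0) == 0) or np.any(grid.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    statistic, p, df, _ = stats.chi2_contingency(grid, correction=False)
    return float(statistic), int(df), float(p)


def read_category_map(tsv_path) -> Dict[str, Set[str]]:
    """gene_id -> set of categories from a two-column TSV (no header)."""
    df = pd.read_csv(tsv_path, sep="\t", header=None, names=["gene_id", "category"])
    out: Dict[str, Set[str]] = {}
    for gid, cat in zip(df["gene_id"].astype(str), df["category"].astype(str)):
        out.setdefault(gid, set()).add(cat)
    return out


def category_report(
    pa_genes: Iterable[str],
    all_genes: Iterable[str],
    category_map: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Per-category P/A counts, proportions and chi-square enrichment tests.

    For each category: ``n_pa`` and ``n_all`` genes carrying it, the P/A rate
    within the category, the category's share among P/A genes, and the
    chi-square test of the 2x2 table (category membership x P/A status) over
    all genes.  With more than one category, BH-adjusted q-values are added.
    """
    pa = set(pa_genes)
    universe = set(all_genes)
    if not any(g in category_map for g in universe):
        raise ValueError("category map covers no gene in the universe")
    categories = sorted({c for g in universe for c in category_map.get(g, ())})
    n_pa_total = len(pa & universe)
    rows = []
    for cat in categories:
        members = {g for g in universe if cat in category_map.get(g, ())}
        a = len(members & pa)
        b = len(members - pa)
        c = n_pa_total - a
        d = len(universe) - len(members) - c
        row = {
            "category": cat,
            "n_pa": a,
            "n_all": len(members),
            "pa_rate_in_category": a / len(members) if members else np.nan,
            "share_of_pa_genes": a / n_pa_total if n_pa_total else np.nan,
        }
        try:
            statistic, _, p = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
            row["chi2"], row["p"] = statistic, p
        except ValueError:
            row["chi2"], row["p"] = np.nan, np.nan
        rows.append(row)
    report = pd.DataFrame(rows).set_index("category")
    if len(report) > 1:
        mask = report["p"].notna()
        q = np.full(len(report), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                report.loc[mask, "p"], method="fdr_bh"
            )[1]
        report["q_bh"] = q
    return report


def frequency_class_share(
    matrix: PAMatrix, gene_set: Iterable[str], lo: int, hi: int
) -> float:
    """Fraction of *gene_set* whose absence count lies in [lo, hi] inclusive."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    counts = matrix.absence_counts
    hits = sum(1 for g in genes if lo <= counts[index[g]] <= hi)
    return hits / len(genes)
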