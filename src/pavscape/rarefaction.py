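"""Random-sampling (rarefaction) model of absent-gene discovery.

How many distinct absent genes do you expect to see among k accessions drawn
from the cohort?  The Monte-Carlo sampler draws accession subsets without
replacement; the closed-form expectation follows from inclusion-exclusion:

    E[count] = sum_g [ 1 - C(n - m_g, k) / C(n, k) ]

with n accessions and m_g the absence count of gene g — the probability that
a sample of size k misses all m_g carriers of the absent allele is
hypergeometric.  The discovery curve is summarized by an ordinary
least-squares fit of the per-size means on ln(size), y = a ln(x) + b, which
supports prediction at unsampled sizes and a randomization test of an
externally observed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .pa_calling import PAMatrix

__all__ = [
    "RarefactionResult",
    "sample_absent_count",
    "sample_absent_counts",
    "expected_absent_count",
    "rarefaction_curve",
    "fit_log_curve",
    "predict_absent",
    "randomization_pvalue",
]


@dataclass
class RarefactionResult:
    """Per-size replicate counts, means, percentile 95% CIs and the log fit."""

    sample_sizes: List[int]
    replicate_counts: Dict[int, np.ndarray]
    means: Dict[int, float]
    ci95: Dict[int, Tuple[float, float]]
    fit_a: float
    fit_b: float


def _check_k(matrix: PAMatrix, k: int) -> None:
    if not 1 <= k <= matrix.n_accessions:
        raise ValueError(
            f"sample size k={k} out of range [1, {matrix.n_accessions}]"
        )


def sample_absent_count(matrix: PAMatrix, k: int, rng: np.random.Generator) -> int:
    """One draw: |{genes absent in >=1 of k uniformly sampled accessions}|."""
    _check_k(matrix, k)
    cols = rng.choice(matrix.n_accessions, size=k, replace=False)
    return int(matrix.absence[:, cols].any(axis=1).sum())


def sample_absent_counts(
    matrix: PAMatrix, k: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized batch of :func:`sample_absent_count` draws.

    Sampling without replacement per replicate is done by argpartition of a
    uniform matrix; the distinct-absent count per replicate comes from one
    boolean matrix product.
    """
    _check_k(matrix, k)
    n = matrix.n_accessions
    # reps x k column indices, each row a uniform k-subset of range(n)
    u = rng.random((reps, n))
    cols = np.argpartition(u, kth=k - 1, axis=1)[:, :k]
    selector = np.zeros((n, reps), dtype=np.float32)
    selector[cols.T, np.arange(reps)] = 1.0
    hits = matrix.absence.astype(np.float32) @ selector  # genes x reps
    return (hits >= 0.5).sum(axis=0).astype(int)


def expected_absent_count(matrix: PAMatrix, k: int) -> float:
    """Exact inclusion-exclusion expectation of the distinct-absent count.

    ``C(n - m, k)`` is taken as 0 when ``k > n - m`` (a sample of that size
    cannot avoid every carrier).
    """
    _check_k(matrix, k)
    n = matrix.n_accessions
    denom = comb(n, k)
    values, counts = np.unique(matrix.absence_counts, return_counts=True)
    total = 0.0
    for m, c in zip(values, counts):
        m = int(m)
        if m == 0:
            continue
        miss = comb(n - m, k) / denom if k <= n - m else 0.0
        total += c * (1.0 - miss)
    return total


def rarefaction_curve(
    matrix: PAMatrix,
    sizes: Sequence[int] | None = None,
    reps: int = 10_000,
    seed: int = 0,
) -> RarefactionResult:
    """Monte-Carlo discovery curve with percentile 95% CIs and the log fit.

    Per size: *reps* independent draws; the CI is the (2.5, 97.5) percentile
    interval of the replicate counts.  Deterministic given *seed*.  The log
    curve is fitted to the per-size means.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if sizes is None:
        sizes = range(1, matrix.n_accessions + 1)
    sizes = [int(k) for k in sizes]
    rng = np.random.default_rng(seed)
    replicate_counts: Dict[int, np.ndarray] = {}
    means: Dict[int, float] = {}
    ci95: Dict[int, Tuple[float, float]] = {}
    for k in sizes:
        counts = sample_absent_counts(matrix, k, reps, rng)
        replicate_counts[k] = counts
        means[k] = float(counts.mean())
        lo, hi = np.percentile(counts, [2.5, 97.5])
        ci95[k] = (float(lo), float(hi))
    a, b = fit_log_curve(sizes, [means[k] for k in sizes])
    return RarefactionResult(sizes, replicate_counts, means, ci95, a, b)


def fit_log_curve(sizes: Sequence[int], means: Sequence[float]) -> Tuple[float, float]:
    """OLS fit of mean counts on ln(size): minimizes sum (y - a ln x - b)^2."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct sample sizes")
    if np.any(x < 1):
        raise ValueError("sample sizes must be >= 1")
    lx = np.log(x)
    design = np.column_stack([lx, np.ones_like(lx)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(a), float(b)


def predict_absent(a: float, b: float, x: float) -> int:
    """``round(a ln x + b)`` to the nearest integer, halves away from zero."""
    if x < 1:
        raise ValueError("x must be >= 1")
    y = a * np.log(x) + b
    return int(np.floor(y + 0.5)) if y >= 0 else int(np.ceil(y - 0.5))


def randomization_pvalue(
    matrix: PAMatrix,
    k: int,
    observed: float,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided randomization p-value for an externally observed count.

    p = fraction of size-k replicate draws whose count deviates from the
    replicate mean by at least |observed - mean|, with an add-one correction
    on numerator and denominator so p is never exactly 0.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    rng = np.random.default_rng(seed)
    counts = sample_absent_counts(matrix, k, reps, rng)
    mean = counts.mean()
    dev = abs(observed - mean)
    extreme = int((np.abs(counts - mean) >= dev).sum())
    return (extreme + 1) / (reps + 1)
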