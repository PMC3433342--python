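"""Nucleotide diversity, frequency binning and the quadratic covariation fit."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pavscape.diversity_covariation import (
    BinSummary,
    LocusDiversity,
    bin_by_frequency,
    covariation_report,
    nucleotide_diversity,
    per_frequency_means,
    quadratic_covariation,
)


class TestNucleotideDiversity:
    def test_identical_pair_is_zero(self):
        assert nucleotide_diversity(["ACGT", "ACGT"]) == 0.0

    def test_one_difference_in_four_sites(self):
        assert nucleotide_diversity(["AAAA", "AAAT"]) == pytest.approx(0.25)

    def test_three_sequences_average_all_pairs(self):
        # pairs: (1,2)=0.25, (1,3)=0.50, (2,3)=0.25 -> mean 1/3
        assert nucleotide_diversity(["AAAA", "AAAT", "AATT"]) == pytest.approx(1 / 3)

    def test_ambiguous_sites_are_pairwise_deleted(self):
        # N site dropped for the pair -> 1 mismatch over 3 comparable sites
        assert nucleotide_diversity(["ANAA", "ACAT"]) == pytest.approx(1 / 3)

    def test_single_sequence_and_unequal_lengths(self):
        assert nucleotide_diversity(["ACGT"]) == 0.0
        with pytest.raises(ValueError, match="unequal"):
            nucleotide_diversity(["ACGT", "ACG"])

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_sequence_order(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(4)
        ]
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert nucleotide_diversity(seqs) == pytest.approx(
            nucleotide_diversity(shuffled)
        )

    def test_copies_of_one_sequence_have_zero_diversity(self):
        assert nucleotide_diversity(["ACGTACGT"] * 5) == 0.0


def _loci(counts, pis=None, lengths=None):
    pis = pis if pis is not None else [0.0] * len(counts)
    lengths = lengths if lengths is not None else [300] * len(counts)
    return [
        LocusDiversity(f"g{i}", m, p, l)
        for i, (m, p, l) in enumerate(zip(counts, pis, lengths))
    ]


class TestBinByFrequency:
    def test_exact_division_fills_equal_bins(self):
        loci = _loci(list(range(1, 11)) * 5)  # 50 loci
        bins = bin_by_frequency(loci, n_accessions=20, n_bins=5, bin_size=10, seed=0)
        assert [len(b.members) for b in bins] == [10] * 5
        freqs = [b.mean_frequency for b in bins]
        assert freqs == sorted(freqs)

    def test_remainder_joins_last_bin(self):
        loci = _loci(list(range(1, 12)))
        bins = bin_by_frequency(loci, n_accessions=12, n_bins=3, bin_size=3, seed=0)
        assert [len(b.members) for b in bins] == [3, 3, 5]
        assert sum(len(b.members) for b in bins) == len(loci)

    def test_no_ties_means_seed_independent_membership(self):
        loci = _loci(list(range(1, 11)))
        a = bin_by_frequency(loci, 12, n_bins=2, bin_size=5, seed=1)
        b = bin_by_frequency(loci, 12, n_bins=2, bin_size=5, seed=99)
        for ba, bb in zip(a, b):
            assert [m.gene_id for m in ba.members] == [m.gene_id for m in bb.members]

    def test_tie_shuffle_is_deterministic_given_seed(self):
        loci = _loci([2] * 20)
        a = bin_by_frequency(loci, 10, n_bins=4, seed=5)
        b = bin_by_frequency(loci, 10, n_bins=4, seed=5)
        for ba, bb in zip(a, b):
            assert [m.gene_id for m in ba.members] == [m.gene_id for m in bb.members]

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            bin_by_frequency(_loci([1, 2]), 10, n_bins=3)


class TestQuadraticCovariation:
    @staticmethod
    def _bins_from(fs, ys):
        return [
            BinSummary(i, [], f, y, 100.0) for i, (f, y) in enumerate(zip(fs, ys))
        ]

    def test_noiseless_quadratic_recovered_with_r_one(self):
        fs = np.linspace(0.05, 0.95, 10)
        ys = 1 + 2 * fs - 2 * fs**2
        fit = quadratic_covariation(self._bins_from(fs, ys))
        assert fit.r == pytest.approx(1.0)
        assert (fit.beta0, fit.beta1, fit.beta2) == pytest.approx((1, 2, -2))
        assert fit.vertex == pytest.approx(0.5)

    def test_constant_response_gives_r_zero(self):
        fs = np.linspace(0.1, 0.9, 8)
        fit = quadratic_covariation(self._bins_from(fs, np.ones(8)))
        assert fit.r == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_coefficients_match_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        fs = np.sort(rng.uniform(0, 1, 12))
        ys = rng.normal(0, 1, 12)
        fit = quadratic_covariation(self._bins_from(fs, ys))
        design = np.column_stack([np.ones(12), fs, fs**2])
        beta = np.linalg.solve(design.T @ design, design.T @ ys)
        assert (fit.beta0, fit.beta1, fit.beta2) == pytest.approx(tuple(beta))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            quadratic_covariation(self._bins_from([0.1, 0.2, 0.3], [1, 2, 3]))


class TestCovariationReport:
    def test_planted_quadratic_law_vertex_recovered(self, default_cohort, called):
        matrix, _ = called
        lengths = {g.gene_id: g.length for g in default_cohort.genes}
        report = covariation_report(
            matrix, default_cohort.alleles, lengths, seed=1, n_bins=10
        )
        fit = report["fit_pi"]
        assert fit.p < 0.01
        assert fit.vertex == pytest.approx(0.5, abs=0.05)

    def test_overall_mean_pi_is_mean_of_locus_pi(self, default_cohort, called):
        matrix, _ = called
        lengths = {g.gene_id: g.length for g in default_cohort.genes}
        report = covariation_report(
            matrix, default_cohort.alleles, lengths, seed=1, n_bins=10
        )
        assert report["mean_pi"] == pytest.approx(
            np.mean([l.pi for l in report["loci"]])
        )
        assert sum(len(b.members) for b in report["bins"]) == len(report["loci"])

    def test_flat_law_rarely_significant(self):
        """Null calibration: a flat diversity law should not show covariation.

        The null spectrum stays below absence count 9 (of 12 accessions) so
        every locus keeps >= 4 present alleles: with 1 present allele pi is 0
        by definition and with 2 it is a single-pair estimate, and those
        degenerate loci would fake a downturn at the high-frequency end.
        """
        from pavscape.pa_calling import build_pa_matrix
        from pavscape.synthetic_data import CohortConfig, generate_cohort

        significant = 0
        n_seeds = 12
        spectrum = {1: 25, 2: 15, 3: 8, 4: 5, 5: 3, 6: 2, 7: 1, 8: 1}
        for s in range(n_seeds):
            cohort = generate_cohort(
                CohortConfig(
                    seed=200 + s,
                    n_genes=120,
                    n_pa_genes=60,
                    deletion_spectrum=spectrum,
                    n_families=6,
                    family_size=4,
                    n_clustered_families=3,
                    n_accessions=12,
                    chromosome_length=600_000,
                    diversity_law=(0.008, 0.0, 0.0),
                    disruption_plan=(2, 2),
                )
            )
            matrix, _ = build_pa_matrix(cohort.genes, cohort.accessions)
            lengths = {g.gene_id: g.length for g in cohort.genes}
            report = covariation_report(
                matrix, cohort.alleles, lengths, seed=s, n_bins=6
            )
            if report["fit_pi"].p < 0.05:
                significant += 1
        assert significant <= max(2, int(0.25 * n_seeds))


def test_per_frequency_means_groups_by_absence_count():
    loci = _loci([1, 1, 2], pis=[0.0, 0.2, 0.4], lengths=[100, 300, 500])
    means = per_frequency_means(loci, 10)
    assert means[1] == (pytest.approx(0.1), pytest.approx(200.0))
    assert means[2] == (pytest.approx(0.4), pytest.approx(500.0))
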