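"""Absence calling, the P/A matrix, spectra, summaries and ORF disruption."""

import numpy as np
import pytest
from conftest import mk_gene, random_pa_matrix
from hypothesis import given
from hypothesis import strategies as st

from pavscape.io_formats import AccessionGenome, Variant, revcomp
from pavscape.pa_calling import (
    PAMatrix,
    absence_spectrum,
    build_pa_matrix,
    call_absent,
    call_disruption,
    false_call_rate,
    inaccessible_fraction,
    per_accession_summary,
)


def brute_force_fraction(gene, mask):
    """Per-base oracle: count CDS bases inside any mask interval."""
    masked = 0
    for s, e in gene.cds_intervals:
        for pos in range(s, e + 1):
            if any(ms <= pos <= me for ms, me in mask.get(gene.chromosome, [])):
                masked += 1
    return masked / gene.length


class TestInaccessibleFraction:
    def test_single_exon_partial_mask(self):
        gene = mk_gene(cds_intervals=((101, 200),))
        assert inaccessible_fraction(gene, {"chr1": [(101, 160)]}) == pytest.approx(0.60)

    def test_splice_aware_two_exon_mask(self):
        # mask (140, 210) covers 11 bases of exon1 (140-150) and 10 of exon2 (201-210)
        gene = mk_gene(cds_intervals=((101, 150), (201, 250)), cds_sequence="A" * 100)
        mask = {"chr1": [(140, 210)]}
        assert inaccessible_fraction(gene, mask) == pytest.approx(0.21)
        assert inaccessible_fraction(gene, mask) == pytest.approx(
            brute_force_fraction(gene, mask)
        )

    def test_empty_and_foreign_chromosome_masks_are_zero(self):
        gene = mk_gene()
        assert inaccessible_fraction(gene, {}) == 0.0
        assert inaccessible_fraction(gene, {"chr9": [(1, 10_000)]}) == 0.0

    @given(st.data())
    def test_matches_per_base_oracle(self, data):
        n_exons = data.draw(st.integers(1, 3))
        intervals, cursor = [], 1
        for _ in range(n_exons):
            start = cursor + data.draw(st.integers(0, 20))
            end = start + data.draw(st.integers(2, 40))  # exon >= one codon
            intervals.append((start, end))
            cursor = end + 2
        gene = mk_gene(cds_intervals=tuple(intervals))
        mask_raw = [
            (s, s + data.draw(st.integers(0, 50)))
            for s in (data.draw(st.integers(1, 120)) for _ in range(data.draw(st.integers(0, 4))))
        ]
        from pavscape.io_formats import merge_intervals

        mask = {"chr1": merge_intervals(mask_raw)}
        assert inaccessible_fraction(gene, mask) == pytest.approx(
            brute_force_fraction(gene, mask)
        )


class TestCallAbsent:
    def test_strictly_more_than_half_is_absent(self):
        gene = mk_gene(cds_intervals=((101, 200),))
        assert call_absent(gene, {"chr1": [(101, 160)]}) is True  # 0.60
        assert call_absent(gene, {"chr1": [(101, 150)]}) is False  # exactly 0.50
        assert call_absent(gene, {}) is False

    @given(st.data())
    def test_monotone_in_the_mask(self, data):
        """Adding mask intervals can never flip absent back to present."""
        gene = mk_gene(cds_intervals=((101, 200),))
        from pavscape.io_formats import merge_intervals

        base = [(s, s + data.draw(st.integers(0, 60)))
                for s in (data.draw(st.integers(80, 220)) for _ in range(2))]
        extra = base + [(data.draw(st.integers(80, 220)), 260)]
        before = call_absent(gene, {"chr1": merge_intervals(base)})
        after = call_absent(gene, {"chr1": merge_intervals(extra)})
        assert not (before and not after)


class TestBuildMatrix:
    @staticmethod
    def _accessions(masks):
        return [
            AccessionGenome(accession_id=f"a{i}", mask=m).normalize()
            for i, m in enumerate(masks)
        ]

    def test_all_absent_genes_go_to_the_discard_report(self):
        g1 = mk_gene("g1", cds_intervals=((101, 200),))
        g2 = mk_gene("g2", cds_intervals=((301, 400),))
        g3 = mk_gene("g3", cds_intervals=((501, 600),))
        accs = self._accessions(
            [
                {"chr1": [(101, 200), (501, 600)]},  # g1, g3 absent
                {"chr1": [(501, 600)]},  # g3 absent
            ]
        )
        matrix, discarded = build_pa_matrix([g1, g2, g3], accs)
        assert matrix.gene_ids == ["g1"]
        assert discarded == ["g3"]  # absent in every accession
        # g2 present everywhere: not a P/A gene at all
        assert "g2" not in matrix.gene_ids and "g2" not in discarded

    def test_absence_counts_match_row_recount(self, called):
        matrix, _ = called
        recount = np.array([(~row).sum() for row in matrix.presence])
        assert np.array_equal(matrix.absence_counts, recount)
        assert matrix.absence_counts.min() >= 1
        assert matrix.absence_counts.max() <= matrix.n_accessions - 1

    def test_duplicate_accession_ids_rejected(self):
        g = mk_gene()
        accs = [AccessionGenome(accession_id="a"), AccessionGenome(accession_id="a")]
        with pytest.raises(ValueError, match="duplicate"):
            build_pa_matrix([g], accs)


class TestSpectrum:
    def test_small_example(self):
        # absence counts per row: 1, 1, 2 -> two singletons, one doubleton
        presence = ~np.array([[1, 0, 0], [1, 0, 0], [1, 1, 0]], bool)
        m = PAMatrix(["g1", "g2", "g3"], ["a", "b", "c"], presence)
        assert absence_spectrum(m) == {1: 2, 2: 1}

    @given(st.integers(0, 2**31 - 1))
    def test_spectrum_sums_to_row_count(self, seed):
        m = random_pa_matrix(np.random.default_rng(seed), 40, 7)
        assert sum(absence_spectrum(m).values()) == m.n_genes

    def test_generated_cohort_spectrum_equals_configured_truth(
        self, default_cohort, called
    ):
        matrix, _ = called
        assert absence_spectrum(matrix) == default_cohort.truth.spectrum


class TestPerAccessionSummary:
    def test_mean_and_proportion(self):
        presence = np.ones((8, 2), bool)
        presence[:3, 0] = False  # accession a: 3 absent
        presence[3:8, 1] = False  # accession b: 5 absent
        m = PAMatrix([f"g{i}" for i in range(8)], ["a", "b"], presence)
        out = per_accession_summary(m, total_genes=100)
        assert out["mean"] == 4.0
        assert (out["min"], out["max"]) == (3, 5)
        assert out["mean_proportion_pct"] == 4.0

    def test_false_call_rate_excludes_uncertain_assays(self):
        assert false_call_rate(11, 53, 9) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            false_call_rate(1, 5, 5)


class TestCallDisruption:
    @staticmethod
    def _clean_gene(strand="+"):
        # 10-codon ORF, no internal stop
        coding = "ATG" + "TGG" + "CAT" * 7 + "TAA"
        genome_fragment = coding if strand == "+" else revcomp(coding)
        return mk_gene(
            "g1",
            strand=strand,
            cds_intervals=((101, 100 + len(coding)),),
            cds_sequence=coding,
        )

    def test_no_variants_is_intact(self):
        assert call_disruption(self._clean_gene(), []).status == "intact"

    def test_one_bp_deletion_is_frameshift(self):
        gene = self._clean_gene()
        v = Variant("chr1", 110, gene.cds_sequence[9:11], gene.cds_sequence[9])
        call = call_disruption(gene, [v])
        assert call.frameshift
        assert call.status in ("frameshift", "both")

    def test_stop_gain_snp_is_premature_stop(self):
        gene = self._clean_gene()
        # codon 2 is TGG at offsets 3-5; TGG -> TGA at the third position
        v = Variant("chr1", 106, "G", "A")
        assert call_disruption(gene, [v]).status == "premature_stop"

    def test_minus_strand_stop_gain(self):
        coding = "ATG" + "TGG" + "CAT" * 7 + "TAA"
        genome = "N" * 100 + revcomp(coding) + "N" * 10
        gene = mk_gene(
            "g1",
            strand="-",
            cds_intervals=((101, 100 + len(coding)),),
            cds_sequence=coding,
        )
        # coding offset 5 (third base of TGG) maps to genomic position
        # end - 5 = 130 - 5 = 125 on the plus strand; plus-strand base is C->T
        plus = revcomp(coding)
        off = len(coding) - 1 - 5
        v = Variant("chr1", 101 + off, plus[off], "T")
        assert call_disruption(gene, [v]).status == "premature_stop"

    def test_frameshift_and_stop_can_cooccur(self):
        gene = self._clean_gene()
        fs = Variant("chr1", 110, gene.cds_sequence[9:11], gene.cds_sequence[9])
        stop = Variant("chr1", 106, "G", "A")
        assert call_disruption(gene, [fs, stop]).status == "both"

    def test_three_bp_deletion_is_in_frame(self):
        gene = self._clean_gene()
        v = Variant("chr1", 107, gene.cds_sequence[6:10], gene.cds_sequence[6])
        call = call_disruption(gene, [v])
        assert not call.frameshift

    def test_ref_mismatch_is_an_error(self):
        gene = self._clean_gene()
        wrong = "T" if gene.cds_sequence[5] != "T" else "C"
        with pytest.raises(ValueError, match="does not match"):
            call_disruption(gene, [Variant("chr1", 106, wrong, "A")])

    def test_overlapping_variants_rejected(self):
        gene = self._clean_gene()
        v1 = Variant("chr1", 105, gene.cds_sequence[4:6], gene.cds_sequence[4])
        v2 = Variant("chr1", 106, gene.cds_sequence[5], "A")
        with pytest.raises(ValueError, match="overlapping"):
            call_disruption(gene, [v1, v2])

    def test_variant_outside_cds_ignored(self):
        gene = self._clean_gene()
        assert call_disruption(gene, [Variant("chr1", 500, "A", "T")]).status == "intact"
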