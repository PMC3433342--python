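"""Shared fixtures: hand-built gene models and the session-wide synthetic cohort.

The default cohort and its (expensive) homology analysis are session-scoped so
the all-vs-all alignment runs once for the whole suite.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pavscape import homology_clusters, pa_calling
from pavscape.io_formats import GeneModel
from pavscape.synthetic_data import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def mk_gene(
    gene_id="g1",
    chromosome="chr1",
    strand="+",
    cds_intervals=((101, 200),),
    cds_sequence=None,
    genome=None,
):
    """GeneModel factory; derives the CDS from *genome* when not given."""
    if cds_sequence is None:
        if genome is not None:
            parts = [genome[s - 1 : e] for s, e in cds_intervals]
            cds_sequence = "".join(parts)
            if strand == "-":
                from pavscape.io_formats import revcomp

                cds_sequence = revcomp(cds_sequence)
        else:
            n = sum(e - s + 1 for s, e in cds_intervals)
            cds_sequence = ("ACGT" * (n // 4 + 1))[:n]
    return GeneModel(gene_id, chromosome, strand, tuple(cds_intervals), cds_sequence)


def random_pa_matrix(rng, n_genes, n_accessions, p_absent=0.2):
    """Random presence grid with every row polymorphic (1 <= m <= n-1)."""
    presence = rng.random((n_genes, n_accessions)) > p_absent
    m = (~presence).sum(axis=1)
    for i in np.flatnonzero(m == 0):
        presence[i, rng.integers(n_accessions)] = False
    for i in np.flatnonzero(m == n_accessions):
        presence[i, rng.integers(n_accessions)] = True
    return pa_calling.PAMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"a{j}" for j in range(n_accessions)],
        presence,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The desk-scale default cohort (400 genes, 20 accessions, seed 0)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def called(default_cohort):
    """(matrix, discarded) from running the absence caller on the cohort."""
    return pa_calling.build_pa_matrix(
        default_cohort.genes, default_cohort.accessions
    )


@pytest.fixture(scope="session")
def family_analysis(default_cohort):
    """(families, singletons, gene order, clusters) on the default cohort."""
    families, singletons = homology_clusters.build_families(default_cohort.genes)
    order = homology_clusters.rank_genes(default_cohort.genes)
    clusters = homology_clusters.detect_clusters(families, order)
    return families, singletons, order, clusters


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for file-emission and CLI tests."""
    return generate_cohort(
        CohortConfig(
            seed=3,
            n_genes=60,
            n_pa_genes=25,
            n_families=5,
            family_size=4,
            n_clustered_families=3,
            n_accessions=8,
            chromosome_length=400_000,
            disruption_plan=(3, 3),
        )
    )
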