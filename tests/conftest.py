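import pytest

from lipomap import annotate, context, profiles, simulate
from lipomap.catalog import HmmCatalog


@pytest.fixture(scope="session")
def catalog() -> HmmCatalog:
    return HmmCatalog.default()


@pytest.fixture(scope="session")
def cohort(catalog):
    """Default synthetic cohort (150 genomes, noise-free), fixed seed."""
    return simulate.generate(simulate.SimSpec(seed=101), catalog)


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A small mixed cohort for faster per-module tests."""
    spec = simulate.SimSpec(
        n_per_type={
            "bac_lipB_lipA": 3,
            "bac_lpl_lipA": 3,
            "bac_slpl_lipS1S2": 3,
            "bac_slpl_lipS1S2_shdr": 2,
            "bac_lipM_lipS1S2": 2,
            "bac_scavenger": 2,
            "bac_none": 2,
            "arc_lplAB_lipS1S2": 3,
            "arc_scavenger": 2,
        },
        seed=202,
    )
    return simulate.generate(spec, catalog)


def annotate_genome(genome, catalog):
    """Annotations, sorted genes, clusters and profile for one sim genome."""
    anns = annotate.annotate_proteome(sorted(genome.sequences), genome.hits, catalog)
    genes = sorted(genome.genes, key=lambda g: (g.contig_id, g.gene_index))
    clusters = context.find_clusters(genes, anns)
    profile = profiles.build_profile(genome.genome_id, anns, genome.taxonomy)
    return anns, genes, clusters, profile


@pytest.fixture(scope="session")
def annotated_small_cohort(small_cohort, catalog):
    return {
        g.genome_id: annotate_genome(g, catalog) for g in small_cohort.genomes
    }
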