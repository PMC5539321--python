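import pytest

from phagepan import genome_io as gio
from phagepan.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 3-group planted cohort shared by the slower integration tests."""
    spec = CohortSpec(
        genomes_per_group=(3, 4, 3),
        core_clusters_per_group=10,
        shared_clusters={(0, 1): 2, (0, 2): 2, (1, 2): 2},
        singleton_rate=0.2,
        gc_targets=(0.56, 0.42, 0.40),
        divergence_within_group=0.05,
        protein_length=(80, 10),
        mesophilic_exceptions=1,
        seed=42,
    )
    outdir = tmp_path_factory.mktemp("cohort")
    paths, truth = generate_cohort(spec, outdir)
    return spec, paths, truth


@pytest.fixture(scope="session")
def small_genomes(small_cohort):
    _, paths, _ = small_cohort
    cohort = gio.load_cohort_table(paths["cohort"])
    return gio.read_genomes(
        [paths["genomes"]], annotation_path=paths["annotations"], cohort=cohort
    )


@pytest.fixture(scope="session")
def small_clusters(small_genomes):
    from phagepan import homology as ho

    hits = ho.all_vs_all(small_genomes)
    all_loci = [f"{g.id}:{l}" for g in small_genomes for l in g.proteins()]
    cog = ho.cog_triangles(ho.bbh_graph(hits), all_loci)
    mcl = ho.mcl_cluster(hits, all_loci)
    return hits, cog, mcl, ho.intersect_clusterings(cog, mcl)


@pytest.fixture(scope="session")
def table1():
    """The bundled 18-phage cohort metadata table."""
    return gio.load_cohort_table()
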