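import pytest

from srnaclassify import (
    build_clusters,
    classify_clusters,
    exclude_rrna,
    filter_multimappers,
    get_preset,
)
from srnaclassify.io_model import MappedRead
from srnaclassify.simulate import SimSpec, simulate_genome, simulate_library


def make_read(
    scaffold="s1",
    start=100,
    length=21,
    strand="+",
    base="U",
    sequence=None,
    count=1,
    n_mappings=1,
):
    """A valid MappedRead with a filler sequence unless one is given."""
    if sequence is None:
        sequence = (base * length)[:length]
    return MappedRead(
        scaffold, start, start + len(sequence), strand, sequence, count, n_mappings
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic dataset: genome, tracks, ground truth, libraries."""
    spec = SimSpec(rng_seed=1)
    genome, tracks, truth = simulate_genome(spec)
    libraries = simulate_library(spec, genome, truth)
    return spec, genome, tracks, truth, libraries


@pytest.fixture(scope="session")
def classified_sim(default_sim):
    """Clusters per stage, classified with the mnemiopsis preset."""
    spec, genome, tracks, truth, libraries = default_sim
    clusters_by_stage = {}
    for stage, lib in libraries.items():
        filtered = filter_multimappers(lib.reads)
        reads = exclude_rrna(filtered.all_reads, tracks["rRNA"])
        clusters = build_clusters(reads)
        classify_clusters(clusters, get_preset("mnemiopsis"), tracks)
        clusters_by_stage[stage] = clusters
    return spec, genome, tracks, truth, clusters_by_stage


@pytest.fixture(scope="session")
def tiny_sim_spec():
    """A small spec for end-to-end pipeline tests."""
    return SimSpec(
        rng_seed=3,
        n_scaffolds=2,
        scaffold_length=20_000,
        n_mirna=4,
        n_endo=4,
        n_pirna=4,
        n_mer25=2,
        n_genes=4,
        n_cisnat_pairs=1,
        n_trna=1,
        n_rrna=1,
        transposon_copy_number=2,
        stages=("s1", "s2"),
    )
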