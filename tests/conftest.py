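import pytest

from mawgs import (
    GeneModel,
    GenomeSpec,
    ReferenceBundle,
    generate_genome,
    study_fixture,
)


@pytest.fixture(scope="session")
def hand_ref():
    """One chromosome with a single hand-built gene ATG TTT GGG TAA on
    the forward strand, flanked by fixed intergenic sequence."""
    flank5 = "CCATTACGGA"
    cds = "ATGTTTGGGTAA"
    flank3 = "TTCAGCATCCGATTAAAC"
    seq = flank5 + cds + flank3
    gene = GeneModel(
        gene_id="g1",
        chromosome="chr1",
        strand="+",
        cds_intervals=((len(flank5) + 1, len(flank5) + len(cds)),),
    )
    return ReferenceBundle(sequences={"chr1": seq}, genes=[gene])


@pytest.fixture(scope="session")
def toy_ref():
    return generate_genome(
        GenomeSpec(n_chromosomes=2, chrom_length=10_000, n_genes=8, seed=11)
    )


@pytest.fixture(scope="session")
def study_exp():
    """Study-shaped synthetic experiment (80 control + 90 treated lines,
    3+1 contaminated dish pairs, 4+3 low-depth lines)."""
    return study_fixture(seed=5)
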