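"""Shared fixtures: synthetic genomes/proteomes generated once per session."""

import pytest

from genostream.simulate import GenomeSpec, generate_genome, generate_pangenome


@pytest.fixture(scope="session")
def metric_genome():
    """200 kb annotated genome with planted paralogs, regulators and rRNA."""
    spec = GenomeSpec(
        genome_id="mg", size_bp=200_000, gc=0.35, seed=7,
        overlap_rate=0.05, stop_bias=(0.8, 0.1, 0.1),
        n_paralog_families=3, paralog_family_size=2,
        n_histidine_kinases=4, n_sigma_factors=3, n_rrna=2,
    )
    genome, proteins, truth = generate_genome(spec)
    return genome, proteins, truth


@pytest.fixture(scope="session")
def small_genome():
    """Small plain genome (no planted features) for alignment-scale tests."""
    spec = GenomeSpec(genome_id="sg", size_bp=60_000, gc=0.40, seed=3,
                      overlap_rate=0.0)
    genome, proteins, truth = generate_genome(spec)
    return genome, proteins, truth


@pytest.fixture(scope="session")
def planted_pangenome():
    """4 genomes, 20 core + 10 accessory families at 70% pairwise identity;
    the first two core families are duplicated in genome G00."""
    proteomes, truth = generate_pangenome(
        4, n_core=20, n_accessory=10, family_identity=0.7,
        n_multicopy_core=2, seed=13)
    return proteomes, truth


@pytest.fixture(scope="session")
def built_families(planted_pangenome):
    from genostream.pangenome import build_families

    proteomes, truth = planted_pangenome
    return build_families(proteomes), truth
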