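import numpy as np
import pytest

from exopair.models import GenomeModel, Arm, Transcript, VariantSite
from exopair.synthetic import SyntheticConfig, generate_all, generate_genome_model


def make_site(**kwargs) -> VariantSite:
    """VariantSite with innocuous defaults; override what the test exercises."""
    defaults = dict(
        chrom="chr1", pos=100, ref="C", alt="T",
        tumor_alt=12, tumor_ref=18, normal_alt=0, normal_ref=30,
        mq0=0, dp=60, qual=200.0, qd=6.0,
    )
    defaults.update(kwargs)
    return VariantSite(**defaults)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small, fast cohort used by most integration-style tests."""
    return SyntheticConfig(
        seed=11, n_early=3, n_advanced=3, n_chromosomes=4,
        arm_length=500_000, genes_per_arm=10,
        mean_tumor_variants=25.0, mean_normal_variants=15.0,
        n_gene_sets=12, gene_set_size=(12, 25),
        go_effect=(("GS000", "advanced", 2.0),),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def default_genome():
    """Genome at the full default study conditions (shared, read-only)."""
    return generate_genome_model(SyntheticConfig(seed=0))


@pytest.fixture()
def toy_genome() -> GenomeModel:
    """Two plus-strand and one minus-strand gene on one tiny chromosome."""
    seq_a = "ATGCGATGGAAATAA"  # M R W K *
    seq_b = "ATGAAACCCGGGTAA"
    seq_c = "TTACCCGGGTTTCAT"  # minus strand: ATG AAA CCC GGG TAA
    transcripts = [
        Transcript("GENE_A", "chrT", "+", 100, 115, seq_a),
        Transcript("GENE_B", "chrT", "+", 200, 215, seq_b),
        Transcript("GENE_C", "chrT", "-", 300, 315, seq_c),
    ]
    arms = [Arm("chrT", "Tp", 0, 250), Arm("chrT", "Tq", 250, 500)]
    return GenomeModel({"chrT": 500}, arms, transcripts)
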