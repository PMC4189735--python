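import numpy as np
import pytest

from anchorprof import (
    CoverageTrack,
    Gene,
    GeneAnnotation,
    SimulationConfig,
    simulate_annotation,
)


@pytest.fixture(scope="session")
def tiny_annotation() -> GeneAnnotation:
    """20 simulated genes on one 500 kb chromosome (deterministic)."""
    cfg = SimulationConfig(
        chrom_sizes={"chr1": 500_000},
        n_genes=20,
        gene_length_range=(2_000, 8_000),
        intergenic_gap_range=(2_000, 10_000),
        seed=101,
    )
    return simulate_annotation(cfg)


@pytest.fixture()
def two_gene_annotation() -> GeneAnnotation:
    """Hand-built two-gene annotation with known coordinates."""
    genes = [
        Gene("plus_gene", "chr1", 1000, 3000, "+", ((1000, 1600), (2400, 3000))),
        Gene("minus_gene", "chr1", 5000, 7000, "-", ((5000, 7000),)),
    ]
    return GeneAnnotation(genes, {"chr1": 20_000})


@pytest.fixture()
def random_track() -> CoverageTrack:
    """A positive random-valued track over a 100 kb chromosome."""
    rng = np.random.default_rng(7)
    return CoverageTrack(values={"chr1": rng.gamma(2.0, 1.0, size=100_000)})
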