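import pytest

import occutarget as ot


@pytest.fixture(scope="session")
def seed7_bundle():
    """The planted-signal study conditions: 200 genes, 15% occupied,
    5e-4 reads/bp background, 40 extra reads per occupied TSS (seed 7)."""
    config = ot.SimulationConfig(seed=7)
    genes, occupied = ot.make_annotation(config)
    reads, peaks = ot.make_reads(genes, occupied, config)
    return config, genes, occupied, reads, peaks


@pytest.fixture
def three_genes():
    return [
        ot.GeneAnnotation("g1", "G1", "chr1", "+", 50_000),
        ot.GeneAnnotation("g2", "G2", "chr1", "-", 150_000),
        ot.GeneAnnotation("g3", "G3", "chr2", "+", 50_000),
    ]
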