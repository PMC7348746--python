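from pathlib import Path

import pytest
from hypothesis import settings

from chipintegrate.genomic_intervals import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
)
from chipintegrate.synthetic_data import simulate

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """A small hand-built annotation exercising strands, exons and CDS.

    chr1: geneA (+, coding, 3 exons) at [10_000, 16_000); geneB (-, coding,
    1 exon) at [40_000, 42_000); geneN (+, non-coding) at [80_000, 82_000).
    chr2: geneC (+) and geneD (-) with TSSs 800 bp apart for tie-breaking.
    chr3: gene-free.
    """
    genes = [
        GeneModel(
            "geneA",
            GenomicInterval("chr1", 10_000, 16_000, "+"),
            (
                GenomicInterval("chr1", 10_000, 11_000, "+"),
                GenomicInterval("chr1", 12_000, 13_000, "+"),
                GenomicInterval("chr1", 15_000, 16_000, "+"),
            ),
            10_500,
            15_500,
        ),
        GeneModel(
            "geneB",
            GenomicInterval("chr1", 40_000, 42_000, "-"),
            (GenomicInterval("chr1", 40_000, 42_000, "-"),),
            40_200,
            41_800,
        ),
        GeneModel(
            "geneN",
            GenomicInterval("chr1", 80_000, 82_000, "+"),
        ),
        GeneModel(
            "geneC",
            GenomicInterval("chr2", 20_000, 24_000, "+"),
        ),
        GeneModel(
            # minus-strand: TSS at 20_799
            "geneD",
            GenomicInterval("chr2", 15_000, 20_800, "-"),
        ),
    ]
    return GenomeAnnotation(
        genes, {"chr1": 200_000, "chr2": 100_000, "chr3": 50_000}
    )


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory) -> Path:
    """A default-scale synthetic input bundle (500 genes, seed 11)."""
    out = tmp_path_factory.mktemp("bundle") / "sim"
    simulate(out, seed=11)
    return out
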