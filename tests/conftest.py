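import numpy as np
import pandas as pd
import pytest

from cisrange.genome_io import Gene, GenomeLayout, PeakSet, Tad


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    """Two chromosomes, three TADs, four genes (one outside all TADs)."""
    tads = [
        Tad("t1", "chr1", 0, 200_000),
        Tad("t2", "chr1", 250_000, 500_000),
        Tad("t3", "chr2", 0, 300_000),
    ]
    genes = [
        Gene("gA", "chr1", 50_000, "+"),
        Gene("gB", "chr1", 300_000, "-"),
        Gene("gC", "chr2", 150_000, "+"),
        Gene("gOut", "chr1", 220_000, "+"),  # in the gap between t1 and t2
    ]
    return GenomeLayout(genes=genes, tads=tads)


def make_peakset(rows, tf_id="TF1", sample_id="TF1_s1") -> PeakSet:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity"])
    return PeakSet(tf_id, sample_id, df)


@pytest.fixture
def tiny_peaks() -> PeakSet:
    # points: 50_000 (x=0 to gA), 60_000 (x=10_000), 310_000 (x=10_000 to gB),
    # 150_000 on chr2 (x=0 to gC)
    return make_peakset(
        [
            ("chr1", 49_900, 50_100, 5.0),
            ("chr1", 59_900, 60_100, 3.0),
            ("chr1", 309_900, 310_100, 4.0),
            ("chr2", 149_900, 150_100, 2.0),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
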