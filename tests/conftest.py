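import numpy as np
import pandas as pd
import pytest

from duplinoise.datatypes import GenomeAnnotation


@pytest.fixture
def toy_annotation():
    """Five '+'-strand genes on one chromosome, well separated."""
    genes = pd.DataFrame(
        [(f"g{i}", "chrI", "+", i * 2000 + 700, i * 2000 + 1500) for i in range(5)],
        columns=["gene", "chrom", "strand", "tss", "end3"],
    )
    return GenomeAnnotation(genes=genes, chrom_lengths={"chrI": 10_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
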