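import pandas as pd
import pytest

from espantools import synthetic


@pytest.fixture(scope="session")
def small_fixture():
    """10 origins + 10 genes on short chromosomes; enough for unit tests."""
    return synthetic.make_genome(
        n_origins=10, n_genes=10, chrom_length=300_000, seed=11
    )


@pytest.fixture
def fragments_df():
    def _make(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mark"])

    return _make
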