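import numpy as np
import pandas as pd
import pytest

from omimgwas.phenotype_mining import TermLexicon
from omimgwas.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def lexicon() -> TermLexicon:
    return TermLexicon.default()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced synthetic study for fast unit tests."""
    return SyntheticConfig(n_variants=4_000, n_reference_samples=500)


def make_variants(rows) -> pd.DataFrame:
    """Rows of (snp, chr, pos, p, maf) -> canonical summary-stat frame."""
    return pd.DataFrame(rows, columns=["snp", "chr", "pos", "p", "maf"])


@pytest.fixture
def make_variants_frame():
    return make_variants


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
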