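import numpy as np
import pytest

from screformer.preprocess import ExpressionTokenizer
from screformer.synthdata import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-marker dataset shared by read-only tests."""
    spec = SyntheticSpec(
        n_cells=300, n_genes=80, n_types=4, markers_per_type=8,
        fold_change=6.0, dropout_rate=0.3, d_embed=24, seed=42,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_tokens(small_dataset):
    tok = ExpressionTokenizer(n_bins=7, vocab=small_dataset.embeddings)
    tok.fit(small_dataset.matrix)
    return tok, tok.transform(small_dataset.matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
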