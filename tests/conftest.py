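import numpy as np
import pytest

from circda.containers import AssociationMatrix, EntityIndex, SimilarityMatrix
from circda.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """Planted dataset small enough for sub-second pipeline runs."""
    config = SyntheticConfig(
        n_circrna=24, m_disease=8, g_genes=12, n_blocks=2,
        seq_len_min=100, seq_len_max=300, seed=7,
    )
    bundle, circ_blocks, dis_blocks = generate_dataset(config)
    return bundle, circ_blocks, dis_blocks


@pytest.fixture
def toy_association():
    """4 circRNAs x 3 diseases with a fixed association pattern."""
    index = EntityIndex(
        ("circA", "circB", "circC", "circD"), ("d1", "d2", "d3")
    )
    values = np.array(
        [[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]], dtype=np.int8
    )
    return AssociationMatrix(values, index)


def identity_similarity(labels):
    return SimilarityMatrix(values=np.eye(len(labels)), labels=tuple(labels))
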