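import numpy as np
import pytest
import scipy.sparse as sp

from cellstab import CountMatrix, flag_genes, generate, presets


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 3 cells with hand-checkable counts."""
    counts = np.array(
        [
            [5, 0, 1],
            [2, 0, 4],
            [0, 0, 3],
        ]
    )
    return CountMatrix(
        gene_ids=np.array(["g1", "g2", "g3"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture
def flagged_matrix() -> CountMatrix:
    """4 genes (1 mito, 2 ribo) x 2 cells, all counts >= detection floor."""
    counts = np.array(
        [
            [3, 0],  # mt-Co1
            [3, 3],  # Rps6
            [3, 3],  # Rpl3
            [3, 3],  # Actb
        ]
    )
    m = CountMatrix(
        gene_ids=np.array(["mt-Co1", "Rps6", "Rpl3", "Actb"], dtype=object),
        cell_ids=np.array(["c1", "c2"], dtype=object),
        counts=sp.csr_matrix(counts),
    )
    return flag_genes(m)


@pytest.fixture(scope="session")
def easy3():
    return generate(presets("easy3"))


@pytest.fixture(scope="session")
def easy2():
    return generate(presets("easy2"))


@pytest.fixture(scope="session")
def stressed_mix():
    return generate(presets("stressed_mix"))
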