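import numpy as np
import pytest

from cyclemark import ExpressionMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 cells x 2 genes with one label per phase."""
    return ExpressionMatrix(
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        gene_ids=["GA", "GB"],
        cell_ids=["c1", "c2", "c3"],
        labels=np.array(["G1", "S", "G2M"], dtype=object),
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but informative dataset: 93 cells x 100 genes, 15 markers."""
    spec = SyntheticSpec(n_per_class=(30, 35, 28), n_genes=100,
                         n_markers_per_class=5, seed=7)
    return generate(spec)
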