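import numpy as np
import pytest

from kgi import (
    ExpressionMatrix,
    GeneSetCollection,
    KnowledgeMatrix,
    PhenotypeVector,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_expr():
    """3 samples x 4 genes with easily hand-checked values."""
    return ExpressionMatrix(
        ["s1", "s2", "s3"],
        ["G1", "G2", "G3", "G4"],
        np.array(
            [
                [2.0, 4.0, 1.0, 0.0],
                [1.0, 2.0, 3.0, 1.0],
                [0.0, 0.0, 2.0, 2.0],
            ]
        ),
    )


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        "KEGG",
        {"SETA": ["G1", "G2"], "SETB": ["G3"], "SETC": ["G1", "G2", "G3"]},
    )


@pytest.fixture
def separable_matrix(rng):
    """120 samples, one feature separated by 3 sd between classes + 2 noise.

    Regenerated from a frozen seed so every test sees the identical draw.
    """
    r = np.random.default_rng(5)
    n = 120
    y = np.r_[np.ones(40, int), np.zeros(80, int)]
    f_sig = np.where(y == 1, r.normal(3.0, 1.0, n), r.normal(0.0, 1.0, n))
    f_n1 = r.normal(0.0, 1.0, n)
    f_n2 = r.normal(0.0, 1.0, n)
    km = KnowledgeMatrix(
        [f"s{i}" for i in range(n)],
        ["FA", "FB", "FC"],
        np.column_stack([f_sig, f_n1, f_n2]),
    )
    labels = PhenotypeVector(km.sample_ids, y)
    return km, labels
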