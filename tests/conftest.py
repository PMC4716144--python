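import numpy as np
import pytest

from keystonekit.io_formats import Corpus, ExpressionMatrix
from collections import Counter


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 groups."""
    rng = np.random.default_rng(0)
    values = 10.0 ** rng.normal(2.5, 0.5, size=(3, 4))
    return ExpressionMatrix(
        ["G1", "G2", "G3"],
        ["a1", "a2", "b1", "b2"],
        values,
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


@pytest.fixture
def toy_corpus() -> Corpus:
    return Corpus(
        {
            "Git2": Counter(["dna", "damage", "repair", "kinase"]),
            "Ins1": Counter(["insulin", "secretion", "glucose", "islet"]),
            "Gapdh": Counter(["glycolysis", "glucose", "metabolism"]),
        }
    )
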