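import numpy as np
import pandas as pd
import pytest

from combistat import ExpressionMatrix, MetadataTable, SampleMetadata


def make_matrix(values, protein_ids=None, sample_ids=None, scale_tag="log2"):
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"P{i+1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids), scale_tag)


def make_metadata(classes, sample_ids=None, batches=None, references=None):
    """classes: list of class labels, one per sample."""
    n = len(classes)
    sample_ids = sample_ids or [f"s{j+1}" for j in range(n)]
    batches = batches or [None] * n
    references = references or [False] * n
    return MetadataTable([
        SampleMetadata(s, c, batch=b, is_reference=r)
        for s, c, b, r in zip(sample_ids, classes, batches, references)
    ])


@pytest.fixture
def small_two_group():
    """3 proteins x 6 samples, two classes, complete log2 matrix."""
    rng = np.random.default_rng(42)
    values = rng.normal(20, 1, size=(3, 6))
    return make_matrix(values), make_metadata(["A"] * 3 + ["B"] * 3)


@pytest.fixture
def correlated_matrix():
    """Complete 200-protein x 6-sample matrix with strong row structure."""
    rng = np.random.default_rng(7)
    base = rng.normal(20, 2, size=(200, 1))
    return make_matrix(base + rng.normal(0, 0.2, size=(200, 6)))
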