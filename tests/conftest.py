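import numpy as np
import pandas as pd
import pytest

from refselect import CqTable, ExpressionMatrix, SampleMetadata


def make_metadata(rows):
    """rows: list of dicts with at least sample_id; missing fields default."""
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def paired_metadata():
    return make_metadata(
        [
            {"sample_id": "P1_N", "group": "Normal", "pair_id": "P1"},
            {"sample_id": "P1_T", "group": "PTC", "pair_id": "P1"},
            {"sample_id": "P2_N", "group": "Normal", "pair_id": "P2"},
            {"sample_id": "P2_T", "group": "PTC", "pair_id": "P2"},
        ]
    )


@pytest.fixture
def small_cq(paired_metadata):
    values = pd.DataFrame(
        {
            "P1_N": [27.0, 30.0],
            "P1_T": [27.0, 28.0],
            "P2_N": [27.0, 31.0],
            "P2_T": [27.0, 29.0],
        },
        index=["REF", "TGT"],
    )
    return CqTable(values=values, metadata=paired_metadata)


def make_expression(values, groups, sexes=None, batches=None):
    """Build an ExpressionMatrix from a 2-D array and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = make_metadata(
        [
            {
                "sample_id": samples[j],
                "group": groups[j],
                "sex": (sexes[j] if sexes else "unknown"),
                "batch": (batches[j] if batches else "b1"),
            }
            for j in range(n_samples)
        ]
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale_tag="log2",
        metadata=meta,
    )
    return matrix, meta
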