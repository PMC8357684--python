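import numpy as np
import pandas as pd
import pytest

from dvx import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def toy_matrix():
    """3 genes x 2 samples with columns (2,4,6) and (3,6,9)."""
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["S1", "S2"],
        values=np.array([[2.0, 3.0], [4.0, 6.0], [6.0, 9.0]]),
        dataset_id="toy",
    )


@pytest.fixture
def two_group_matrix():
    """One gene, two groups of three samples with distinct spreads."""
    values = np.array([[8.0, 10.0, 12.0, 5.0, 10.0, 15.0]])
    matrix = ExpressionMatrix(
        gene_ids=["G1"],
        sample_ids=[f"S{i}" for i in range(1, 7)],
        values=values,
        dataset_id="toy",
    )
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(1, 7)],
                "group_label": ["A"] * 3 + ["B"] * 3,
                "dataset_id": "toy",
            }
        )
    )
    return matrix, annotation


def write_matrix_tsv(path, gene_ids, sample_ids, rows):
    lines = ["gene_id\t" + "\t".join(sample_ids)]
    for gid, row in zip(gene_ids, rows):
        lines.append(gid + "\t" + "\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
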