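import numpy as np
import pandas as pd
import pytest

from fpkmkit.expression import ExpressionMatrix, SampleTable


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = np.array([[1.0, 2.0], [0.0, 0.0], [5.0, 1.0]])
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["s1", "s2"])


@pytest.fixture
def cohort():
    """A 20-gene cohort with the study's group sizes and two batches."""
    rng = np.random.default_rng(42)
    n_genes = 20
    sample_ids = (
        [f"control_{i}" for i in range(1, 6)]
        + [f"AD_{i}" for i in range(1, 7)]
        + [f"PD_{i}" for i in range(1, 4)]
    )
    groups = ["control"] * 5 + ["AD"] * 6 + ["PD"] * 3
    batches = ["session1" if i % 2 == 0 else "session2" for i in range(14)]
    values = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, 14))
    matrix = ExpressionMatrix(values, [f"g{i:02d}" for i in range(n_genes)], sample_ids)
    meta = SampleTable(
        pd.DataFrame({"sample_id": sample_ids, "group": groups, "batch": batches})
    )
    return matrix, meta


def write_tsv(path, text):
    path.write_text(text)
    return path
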