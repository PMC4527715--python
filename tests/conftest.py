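import numpy as np
import pandas as pd
import pytest

from envepi.io import FoldChangeMatrix


def make_matrix(values_by_condition: dict[str, np.ndarray],
                feature_ids=None) -> FoldChangeMatrix:
    """Build a FoldChangeMatrix from per-condition replicate blocks.

    ``values_by_condition`` maps "A"/"B"/"AB" to (n_features x n_rep) arrays.
    """
    blocks, ids, sa, sb, rep = [], [], [], [], []
    design = {"A": (1, 0), "B": (0, 1), "AB": (1, 1)}
    for label in ("A", "B", "AB"):
        arr = np.atleast_2d(np.asarray(values_by_condition[label], float))
        blocks.append(arr)
        for r in range(arr.shape[1]):
            ids.append(f"{label}_r{r + 1}")
            sa.append(design[label][0])
            sb.append(design[label][1])
            rep.append(r + 1)
    data = np.hstack(blocks)
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(data.shape[0])]
    samples = pd.DataFrame(
        {"stimulus_a": sa, "stimulus_b": sb, "replicate": rep},
        index=pd.Index(ids, name="sample_id"),
    )
    return FoldChangeMatrix(
        values=pd.DataFrame(
            data, index=pd.Index(feature_ids, name="feature_id"), columns=ids
        ),
        samples=samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def nine_point_matrix():
    """One feature: A (0.9, 1.0, 1.1), B (-0.1, 0, 0.1), AB (0.9, 1.0, 1.1)."""
    return make_matrix(
        {
            "A": [[0.9, 1.0, 1.1]],
            "B": [[-0.1, 0.0, 0.1]],
            "AB": [[0.9, 1.0, 1.1]],
        }
    )
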