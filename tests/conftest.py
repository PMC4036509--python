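import numpy as np
import pandas as pd
import pytest

from nitroroot import ExpressionMatrix


def make_matrix(values: np.ndarray, r: int = 3) -> ExpressionMatrix:
    """Wrap a (n_genes, 4*r) array as a balanced matrix.

    Column blocks follow (WT-HN, WT-LN, MUT-HN, MUT-LN), r replicates each.
    """
    sample_ids, rows = [], []
    for g in ("WT", "MUT"):
        for n in ("HN", "LN"):
            for k in range(1, r + 1):
                sample_ids.append(f"{g}_{n}_{k}")
                rows.append({"genotype": g, "nitrate": n, "replicate": k})
    probe_ids = [f"gene_{i + 1}" for i in range(values.shape[0])]
    # reorder from (WT-HN, WT-LN, MUT-HN, MUT-LN) blocks to the sample order above
    frame = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    design = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values=frame, design=design)


@pytest.fixture
def worked_example_matrix() -> ExpressionMatrix:
    """The r=2 hand-checked gene: WT-HN {10,12}, WT-LN {9,11}, MUT-HN {14,16},
    MUT-LN {13,15}."""
    values = np.array([[10.0, 12.0, 9.0, 11.0, 14.0, 16.0, 13.0, 15.0]])
    return make_matrix(values, r=2)
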