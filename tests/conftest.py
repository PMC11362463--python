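import numpy as np
import pandas as pd
import pytest

from hccdriver.datasets import StageDataset
from hccdriver.single_cell import CellMatrix


@pytest.fixture
def tiny_stage_dataset() -> StageDataset:
    """3 stages x 2 samples, 3 genes: one rising, one flat, one falling."""
    genes = ["FALL", "FLAT", "RISE"]
    samples = [f"s{i}" for i in range(6)]
    expr = pd.DataFrame(
        [
            [6.0, 5.9, 5.0, 4.9, 4.0, 3.9],  # falling
            [5.0, 5.1, 5.0, 4.9, 5.05, 5.0],  # flat
            [4.0, 4.1, 5.0, 5.1, 6.0, 6.1],  # rising
        ],
        index=genes,
        columns=samples,
    )
    stage = pd.Series(["NL", "NL", "LC", "LC", "aHCC", "aHCC"], index=samples)
    return StageDataset(expr, stage, cohort_id="tiny")


@pytest.fixture
def small_cells() -> CellMatrix:
    """Four samples x three cells, three genes with hand-checkable counts."""
    rng = np.random.default_rng(7)
    cells = [f"S{j}_c{k}" for j in range(1, 5) for k in range(3)]
    counts = pd.DataFrame(
        rng.poisson(3.0, size=(12, 3)),
        index=pd.Index(cells, name="cell"),
        columns=["GA", "GB", "GC"],
    )
    sample = pd.Series([c.split("_")[0] for c in cells], index=counts.index)
    phen = pd.Series(
        ["malignant" if s in {"S1", "S2"} else "normal" for s in sample], index=counts.index
    )
    return CellMatrix(counts, sample, phen)
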