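import numpy as np
import pandas as pd
import pytest

from rgstab import CqTable, ExpressionMatrix, Scale


@pytest.fixture
def small_cq_df() -> pd.DataFrame:
    """2 genes x 2 samples x 2 replicates, one group each sample."""
    rows = []
    for gene, base in (("g1", 30.0), ("g2", 28.0)):
        for sample, group in (("s1", "red"), ("s2", "green")):
            for rep, jitter in ((1, 0.0), (2, 1.0)):
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "cq": base + jitter,
                        "efficiency": 2.0,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def small_cq_table(small_cq_df) -> CqTable:
    return CqTable(data=small_cq_df, experiment_id="unit")


def make_matrix(values: dict[str, list[float]], scale=Scale.CQ, groups=None) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    groups = groups or {c: "all" for c in df.columns}
    return ExpressionMatrix(values=df, scale=scale, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
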