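import numpy as np
import pandas as pd
import pytest

from stemscore import ExpressionMatrix, GeneSetCollection, SurvivalTable


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    genes = [f"g{i:03d}" for i in range(30)]
    samples = [f"s{i}" for i in range(8)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(6, 2, (30, 8)), index=genes, columns=samples)
    )


@pytest.fixture
def small_sets(small_expr) -> GeneSetCollection:
    genes = small_expr.gene_ids
    return GeneSetCollection(
        {"top": genes[:5], "mid": genes[10:16], "tail": genes[-5:]}, "fixture"
    )


@pytest.fixture
def exp_surv() -> SurvivalTable:
    rng = np.random.default_rng(7)
    n = 40
    t = rng.exponential(10, n).round(3)
    e = (rng.random(n) < 0.8).astype(int)
    return SurvivalTable(
        pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(n)])
    )
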