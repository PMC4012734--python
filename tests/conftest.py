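import numpy as np
import pandas as pd
import pytest

from coexsurv import ExpressionMatrix, SurvivalTable


def make_matrix(values, probes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


def make_survival(times, events, ids=None) -> SurvivalTable:
    ids = ids or [f"S{i+1}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"sample_id": ids, "time": times, "event": events})
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix():
    return make_matrix([[10.0, 20.0, 5.0, 7.5],
                        [1.0, 2.0, 3.0, 4.0],
                        [100.0, 50.0, 25.0, 12.5]])
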