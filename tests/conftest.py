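import numpy as np
import pandas as pd
import pytest

import emtdyn as e


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 8 modules x 120 genes + 240 background,
    noise SD 0.3, both stage grids."""
    cfg = e.default_config(seed=11)
    Xa, Xb, truth = e.generate_timeseries_pair(cfg)
    return {"cfg": cfg, "Xa": Xa, "Xb": Xb, "truth": truth}


def detect(X, min_size=30, beta=6, mode="signed"):
    corr = e.correlation_matrix(X)
    adj = e.adjacency(corr, beta, mode=mode)
    tom = e.tom_similarity(adj)
    part = e.detect_modules(tom, min_size=min_size, expr=X)
    eig = e.module_eigengenes(X, part)
    return part, eig


@pytest.fixture(scope="session")
def detected(study):
    """Module partitions and eigengenes for both datasets of the study."""
    out = {}
    for tag in ("a", "b"):
        part, eig = detect(study[f"X{tag}"])
        out[tag] = {"part": part, "eig": eig}
    return out


@pytest.fixture()
def tiny_timeseries():
    """A handmade 4-gene, 5-stage matrix with known correlations."""
    hours = [0.0, 2.0, 8.0, 24.0, 72.0]
    df = pd.DataFrame(
        {
            "g1": [1.0, 2.0, 3.0, 4.0, 5.0],
            "g2": [2.0, 4.0, 6.0, 8.0, 10.0],   # r(g1, g2) = 1
            "g3": [5.0, 4.0, 3.0, 2.0, 1.0],    # r(g1, g3) = -1
            "g4": [1.0, 3.0, 2.0, 5.0, 4.0],
        }
    ).T
    df.columns = hours
    return e.TimeSeriesMatrix(df)
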