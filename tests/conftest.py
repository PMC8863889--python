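import numpy as np
import pandas as pd
import pytest

from cebu.datatypes import AlignedDataset, SyntheticConfig
from cebu.synthetic import emit_ground_truths, generate


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study conditions: 200 cells, 10 tissues,
    100 x 100 pair universe with 50 planted pairs."""
    cfg = SyntheticConfig(seed=20240101)
    data, truth = generate(cfg)
    ground = emit_ground_truths(truth, cfg)
    return cfg, data, truth, ground


@pytest.fixture(scope="session")
def fitted(default_bundle):
    """CScoreModel + full-universe results on the default bundle."""
    from cebu.cscore import CScoreModel

    _, data, _, _ = default_bundle
    model = CScoreModel(data)
    results = model.fit(threshold=-np.inf)
    return model, results


@pytest.fixture
def tiny_dataset():
    """Hand-built 4-gene x 6-cell dataset, 2 tissues, no noise structure."""
    cells = [f"c{i}" for i in range(6)]
    rng = np.random.default_rng(7)
    dep = pd.DataFrame(rng.normal(-0.5, 0.3, size=(4, 6)),
                       index=["d1", "d2", "d3", "d4"], columns=cells)
    expr = pd.DataFrame(rng.uniform(1, 8, size=(4, 6)),
                        index=["e1", "e2", "e3", "e4"], columns=cells)
    # one exactly linear pair (d1, e4) so a significant positive
    # correlation — and hence slope_min — always exists
    expr.loc["e4"] = 3.0 + dep.loc["d1"]
    ann = pd.Series(["tA", "tA", "tA", "tB", "tB", "tB"], index=cells,
                    name="tissue_type")
    return AlignedDataset(dep, expr, ann)
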