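import pandas as pd
import pytest

import chronogauge as cg
from chronogauge.io_scaling import ExpressionMatrix


@pytest.fixture(scope="session")
def training_sim():
    """Default 4-experiment training-like study with ground truth."""
    return cg.make_training_like(seed=1)


@pytest.fixture(scope="session")
def heldout_sim():
    """Held-out samples sharing gene truth with training_sim."""
    return cg.make_test_like(seed=1)


@pytest.fixture(scope="session")
def tiny_ensemble(training_sim):
    """A very small but real ensemble for unit-level checks."""
    import warnings

    m, truth = training_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        e = cg.ChronoGaugeEnsemble(
            n_runs=3, sfs_budget=16, tuning_trials=1, base_seed=100,
            sfs_epochs=40, final_epochs=80, top_n=3,
        )
        e.fit(m, cg.filter_circadian(truth))
    return e


def small_matrix(values, times_h, light="LL", experiment="exp0"):
    """Helper constructing an ExpressionMatrix from a dict of rows."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame(
        {
            "time_h": times_h,
            "experiment_id": experiment,
            "light_regime": light,
            "platform": "rnaseq",
        },
        index=df.columns,
    )
    return ExpressionMatrix(df, meta)
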