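import numpy as np
import pandas as pd
import pytest

import exonsplice as xs


@pytest.fixture(scope="session")
def sim_small():
    """A small spiked chip shared across tests (deterministic)."""
    cfg = xs.SimConfig(
        seed=11, n_genes=40, f_de=0.1, f_as=0.1, bg_probes_per_bin=40,
        delta_de=1.0, delta_as=2.0,
    )
    return xs.simulate_chip(cfg)


@pytest.fixture(scope="session")
def sim_small_state():
    """Full analysis state of a small spiked chip."""
    cfg = xs.PipelineConfig.from_dict(
        {
            "simulate": {
                "seed": 11, "n_genes": 40, "f_de": 0.1, "f_as": 0.1,
                "bg_probes_per_bin": 40, "delta_de": 1.0, "delta_as": 2.0,
            }
        }
    )
    return xs.analyze(cfg)


@pytest.fixture()
def toy_design():
    """Two groups of two arrays."""
    return xs.GroupDesign(
        pd.Series(
            ["g1", "g1", "g2", "g2"],
            index=pd.Index(["a1", "a2", "a3", "a4"], name="array_id"),
        )
    )


def make_background_model(
    gcs=(10,), median=0.0, mean=0.0, var=1.0, var_avg=1.0, total_var=1.0
):
    """Hand-built background model for unit tests."""
    bins = pd.DataFrame(
        {
            "median": [median] * len(gcs),
            "mean": [mean] * len(gcs),
            "var": [var] * len(gcs),
            "n": [100] * len(gcs),
        },
        index=pd.Index(gcs, name="gc"),
    )
    gbm = pd.DataFrame({"mean": []})
    return xs.BackgroundModel(bins, var_avg, total_var, gbm)
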