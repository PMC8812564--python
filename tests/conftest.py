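import warnings

import numpy as np
import pandas as pd
import pytest

from reefexo.classify import classify_features
from reefexo.pipeline import PipelineConfig, run_pipeline
from reefexo.synthetic import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration synthetic experiment (seed 1)."""
    return generate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_cascade(default_sim):
    return classify_features(default_sim.feature_table, default_sim.metadata)


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Full pipeline result on the default synthetic experiment."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=1), simulate=SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_feature_fixture(rng, n_features=50, seed_tag=""):
    """Small random experiment-shaped table for brute-force oracle tests.

    Intensities are drawn broadly across the filter-relevant range so every
    cascade rule sees both sides of its threshold.
    """
    from reefexo.io import FeatureTable
    from reefexo.synthetic import SimulationConfig, _build_metadata

    meta = _build_metadata(SimulationConfig())
    samples = meta["sample_id"].tolist()
    log10 = rng.uniform(2.0, 7.0, size=(n_features, len(samples)))
    data = pd.DataFrame(10.0 ** log10,
                        index=[f"R{i}" for i in range(n_features)], columns=samples)
    # sprinkle exact zeros (gap fill) and sub-threshold cells
    mask = rng.random(data.shape) < 0.15
    data = data.mask(pd.DataFrame(mask, index=data.index, columns=data.columns), 0.0)
    return FeatureTable(data), meta
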