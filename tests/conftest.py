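import numpy as np
import pandas as pd
import pytest

from omicnet.io import FeatureMatrix, SampleDesign
from omicnet.simulate import SimulationConfig, simulate_dataset, simulate_design


def make_design(n_variety=2, n_location=2, n_stage=2, n_rep=2) -> SampleDesign:
    cfg = SimulationConfig(design=(n_variety, n_location, n_stage, n_rep))
    return simulate_design(cfg)


def small_config(**overrides) -> SimulationConfig:
    """Compact dataset for fast tests: 5 gene modules of 30, 4 metabolite
    modules of 15, full 3x3x6x2 design."""
    params = dict(
        n_genes=400,
        n_metabolites=150,
        module_size_gene=30,
        module_size_metab=15,
        seed=0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def design_2x2x2() -> SampleDesign:
    return make_design(2, 2, 2, 2)


@pytest.fixture(scope="session")
def design_3x3x6() -> SampleDesign:
    return make_design(3, 3, 6, 2)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


def random_matrix(n_features=10, n_samples=8, seed=0, kind="transcript") -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_features, n_samples)),
        index=[f"F{i:03d}" for i in range(n_features)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return FeatureMatrix(df, kind)
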