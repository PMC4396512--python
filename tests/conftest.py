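import numpy as np
import pandas as pd
import pytest

from glucotype import (
    DEFAULT_PARAMS,
    TABLE2_GENOTYPES,
    SplitPlotDesign,
    TrialConfig,
    generate_trial,
    predict_profile,
)
from glucotype.pathway_model import ALIPHATIC_STRUCTURES


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def table2():
    return TABLE2_GENOTYPES


@pytest.fixture(scope="session")
def genotype_mean_profiles():
    """Noise-free aliphatic mean profiles of the 17-genotype population."""
    rows = {
        name: {
            s: predict_profile(geno).get(s) for s in ALIPHATIC_STRUCTURES
        }
        for name, geno in TABLE2_GENOTYPES.items()
    }
    return pd.DataFrame(rows).T


@pytest.fixture(scope="session")
def small_design():
    """A reduced split-plot layout for fast model tests."""
    return SplitPlotDesign(n_genotypes=4, blocks_per_plot=3)


@pytest.fixture(scope="session")
def default_trial():
    return generate_trial(TrialConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
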