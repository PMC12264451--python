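import warnings

import numpy as np
import pytest

from tpenet.metabolic import build_nc_reference
from tpenet.pipeline import StudyConfig, run_study
from tpenet.synthetic import (
    gen_nc_uptake, null_effect_specs, strong_effect_specs,
)


@pytest.fixture(scope="session")
def nc_reference():
    return build_nc_reference(gen_nc_uptake(52, seed=7))


@pytest.fixture(scope="session")
def strong_study():
    """Desk-scale end-to-end run with the fully expressed insular phenotype."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = StudyConfig.desk_scale(effect_specs=strong_effect_specs())
        return run_study(cfg, seed=101)


@pytest.fixture(scope="session")
def null_study():
    """Desk-scale end-to-end run with every implanted effect zeroed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = StudyConfig.desk_scale(
            effect_specs=null_effect_specs(),
            eeg_determinism={"TLE": 0.5, "TPE": 0.5},
        )
        return run_study(cfg, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
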