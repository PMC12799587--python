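import numpy as np
import pytest

from scepharm.synthetic import (
    DEFAULT_FUNCTIONAL_GRID,
    GroundTruth,
    SimulationConfig,
)


@pytest.fixture
def grid():
    return np.asarray(DEFAULT_FUNCTIONAL_GRID)


@pytest.fixture
def two_conf_config():
    """A minimal two-conformation panel: a full CCE agonist, an SCE partial
    agonist with high-affinity CCE antagonism, a neutral antagonist, a
    biphasic agonist and a non-binder."""
    truth = (
        GroundTruth("ref_agonist", "cce_agonist", logKd_cce=-6.43, efficacy_cce=0.97),
        GroundTruth("sce_partial", "sce_agonist", logKd_cce=-9.77,
                    logKd_sce=-7.20, efficacy_sce=0.542),
        GroundTruth("blocker", "neutral", logKd_cce=-9.47, logKd_sce=-7.37),
        GroundTruth("both_sites", "biphasic", logKd_cce=-9.24, efficacy_cce=0.2,
                    logKd_sce=-7.16, efficacy_sce=0.178),
        GroundTruth("inert", "nonbinder"),
    )
    return SimulationConfig(ground_truth=truth, seed=7, cell_line="test_line")


@pytest.fixture
def noiseless(two_conf_config):
    import dataclasses

    return dataclasses.replace(two_conf_config, noise_sd=0.0)
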