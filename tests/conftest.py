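import numpy as np
import pandas as pd
import pytest

from imprintscan.io_model import BetaMatrix, SampleSheet
from imprintscan.synthetic_data import (SimulationConfig, simulate_bundle,
                                        write_bundle)


@pytest.fixture
def small_sheet():
    return SampleSheet(pd.DataFrame({
        "sample_id": ["C1", "C2", "C3", "P1", "P1c1"],
        "role": ["control", "control", "control", "patient", "corrected"],
        "parent_patient": [None, None, None, None, "P1"],
        "cell_type": ["iPSC"] * 5,
    }))


@pytest.fixture
def tiny_beta():
    return BetaMatrix(pd.DataFrame(
        {"C1": [0.50, 0.90, 0.10],
         "C2": [0.52, 0.88, 0.12],
         "C3": [0.48, 0.92, 0.11],
         "P1": [0.50, 0.45, 0.10],
         "P1c1": [0.50, 0.89, 0.10]},
        index=["u1", "u2", "u3"]))


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(default_bundle, d)
    return d


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*sd_m = 0.*")
        warnings.filterwarnings("ignore", message=".*missing in at least one control.*")
        yield
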