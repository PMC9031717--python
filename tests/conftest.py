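import warnings

import numpy as np
import pytest

from emca.melt import DuplexSpec, MismatchPenaltySet
from emca.swv import FerrocenePeakModel, SWVParams


@pytest.fixture(autouse=True)
def _quiet_sample_interval_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="sample_interval exceeds tau/10"
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def full_duplex():
    return DuplexSpec(name="wt", allele="full", surface_tm=37.0, vant_hoff_enthalpy=300.0)


@pytest.fixture
def default_penalties():
    return MismatchPenaltySet()


@pytest.fixture
def clean_peak():
    return FerrocenePeakModel(noise_sd=0.0)


@pytest.fixture
def swv_params():
    return SWVParams()
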