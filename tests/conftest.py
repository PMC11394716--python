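import numpy as np
import pytest

import nironline as nl


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: 120 offline + 75 drifted online samples."""
    return nl.generate_study(nl.SimConfig())


@pytest.fixture(scope="session")
def offline_artifacts(default_study):
    """Offline calibration pipeline run once on the default study."""
    return nl.fit_offline(default_study.offline, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
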