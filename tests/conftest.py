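import pytest
from hypothesis import settings

import ccmscan as ccm

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return ccm.load_default_panel()


@pytest.fixture(scope="session")
def default_study():
    """One default-condition simulated study run through the full pipeline.

    Session-scoped: the normalization, QC, PCA and differential checks all
    interrogate the same run, exactly as they would a single acquisition.
    """
    spec = ccm.RunSpec(seed=20)
    return ccm.run_inhibitor_study(seed=20, spec=spec), spec


@pytest.fixture(scope="session")
def default_calibration(default_study):
    _, spec = default_study
    return ccm.run_calibration(spec=spec)
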