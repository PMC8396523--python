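import pytest

import mabquant as mq


@pytest.fixture(scope="session")
def panel_run():
    """Zero-noise originator-like synthetic run with its truth and library."""
    config, library = mq.preset_glycoform_panel(seed=7)
    run, truth = mq.simulate_run(config)
    return run, truth, library


@pytest.fixture(scope="session")
def kvariant_run():
    """Zero-noise three-lysine-ladder synthetic run."""
    config, library = mq.preset_rituximab_like(seed=11)
    run, truth = mq.simulate_run(config)
    return run, truth, library
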