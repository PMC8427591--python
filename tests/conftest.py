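import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_sheet():
    from cotupipe.io_formats import SampleSheet
    return SampleSheet({"A": "ACGTACGTAC", "B": "TGCATGCATG"})


@pytest.fixture
def panel_primers():
    from cotupipe.barcodes import PANEL
    from cotupipe.io_formats import PrimerSpec, PrimerTable
    return PrimerTable({
        f.gene: PrimerSpec(f.fwd, f.rev, *f.expected_len) for f in PANEL
    })
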