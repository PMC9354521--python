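import pytest
from hypothesis import settings as hyp_settings

from mesocea import base_case

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")
from mesocea.model import CHEMO_OS, CHEMO_PFS, NIVO_IPI_OS, NIVO_IPI_PFS

BASE_DISTS = {
    "nivo_ipi_os": NIVO_IPI_OS,
    "nivo_ipi_pfs": NIVO_IPI_PFS,
    "chemo_os": CHEMO_OS,
    "chemo_pfs": CHEMO_PFS,
}


@pytest.fixture(scope="session")
def model():
    """The shipped base case (session-scoped; callers must not mutate it —
    use ``model.with_parameters`` for variants)."""
    return base_case()


@pytest.fixture(scope="session")
def outcome(model):
    """Base-case arm results and incremental comparison."""
    return model.run()
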