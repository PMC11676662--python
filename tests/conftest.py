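import pytest

from hlacc.cohort import select_subgroup
from hlacc.refdata import (
    load_national_frequencies,
    load_reference_cohort,
    load_reference_panel,
)


@pytest.fixture(scope="session")
def ref_cohort():
    """The frozen 40-subject reconstructed cohort shipped with the package."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def panel_lowres():
    return load_reference_panel(1)


@pytest.fixture(scope="session")
def panel_highres():
    return load_reference_panel(2)


@pytest.fixture(scope="session")
def national_freqs():
    return load_national_frequencies()


@pytest.fixture(scope="session")
def dsn_cohort(ref_cohort):
    return select_subgroup(ref_cohort, {"serotype": "dSNMG"})


@pytest.fixture(scope="session")
def rach_cohort(ref_cohort):
    return select_subgroup(ref_cohort, {"serotype": "RAchPos"})
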