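import numpy as np
import pytest

from beltdiv import OccurrenceRecord, load_fixture_table3


@pytest.fixture(scope="session")
def table3():
    """Packaged 13-species x 3-plantation presence fixture + taxonomy."""
    return load_fixture_table3()


@pytest.fixture()
def toy_records():
    """Two species across two sections of one transect."""
    return [
        OccurrenceRecord("S1", "1", "Odontotermes grandiceps",
                         "Odontotermes", "IIf"),
        OccurrenceRecord("S1", "2", "Odontotermes grandiceps",
                         "Odontotermes", "IIf"),
        OccurrenceRecord("S1", "2", "Pericapritermes mohri",
                         "Pericapritermes", "III"),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20210328)
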