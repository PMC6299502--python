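import math

import pytest

from cessmiss import ArmCounts, TrialCounts, enhanced_quit_win_fixture

OR_GRID = (1.0, 2.0, 3.0, 4.0, 5.0, math.inf)


@pytest.fixture(scope="session")
def quit_win() -> TrialCounts:
    return enhanced_quit_win_fixture()


@pytest.fixture
def no_missing_arm() -> ArmCounts:
    """An arm with complete data at both stages."""
    return ArmCounts("A", 100, 30, 70, 0, 25.0, 5.0, 0.0)
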