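import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from vsalert.ews import ThresholdConfig


@pytest.fixture(scope="session")
def cfg() -> ThresholdConfig:
    """Default rule table: yellow 140/90, red 160/110, SI 0.9/1.7, inclusive."""
    return ThresholdConfig()


@pytest.fixture(scope="session")
def strict_cfg() -> ThresholdConfig:
    return ThresholdConfig(inclusive_boundaries=False)
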