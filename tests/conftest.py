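import sys
from dataclasses import replace
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from foragerisk.config import SimConfig
from foragerisk.pipeline import StudyData, simulate_study


@pytest.fixture(scope="session")
def default_study() -> StudyData:
    """One full synthetic study run under default conditions (seed 1)."""
    return simulate_study(config=replace(SimConfig(), seed=1))


@pytest.fixture(scope="session")
def noise_free_study() -> StudyData:
    """Noise-free study: no fix dropout, seed-fixed (segmentation checks)."""
    return simulate_study(config=replace(SimConfig(), dropout=0.0, seed=1))
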