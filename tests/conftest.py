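import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from halophb.synthetic import (
    AMMONIUM_MEDIUM,
    DEFAULT_MEDIUM,
    ToyModelSpec,
    build_mini_halo,
)


@pytest.fixture(scope="session")
def mini_halo():
    return build_mini_halo()


@pytest.fixture(scope="session")
def mini_halo_no_phb():
    return build_mini_halo(ToyModelSpec(include_phb=False))


@pytest.fixture()
def default_medium():
    return dict(DEFAULT_MEDIUM)


@pytest.fixture()
def ammonium_medium():
    return dict(AMMONIUM_MEDIUM)


@pytest.fixture()
def aerobic_medium():
    """Glucose + glutamate with oxygen unbounded (for forced-uptake work)."""
    return {"EX_glc": (-10.0, 0.0), "EX_glu": (-2.0, 0.0),
            "EX_o2": (-1000.0, 0.0)}
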