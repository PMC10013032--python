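from __future__ import annotations

import json
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repro")

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = Path(__file__).resolve().parent / "data"


@pytest.fixture(scope="session")
def hand_trace() -> dict:
    """Pre-registered manual walk of the acute pain-reflex path."""
    return json.loads((DATA_DIR / "pain_reflex_hand_trace.json").read_text())


@pytest.fixture(scope="session")
def examples_dir() -> Path:
    return REPO_ROOT / "examples"


@pytest.fixture
def fop111():
    from fopnet import FOPConfig, build_fop_net

    return build_fop_net(FOPConfig(m=1, n=1, p=1))
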