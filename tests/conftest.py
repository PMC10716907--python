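import json

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    from qtdg import load_pattern_library

    return load_pattern_library()


@pytest.fixture(scope="session")
def butane():
    from qtdg import make_toy_molecule

    return make_toy_molecule("butane")


@pytest.fixture
def write_library(tmp_path):
    """Write a list of (smarts, kind) records to a JSON library file."""

    def _write(records, name="mini.json"):
        path = tmp_path / name
        path.write_text(json.dumps({
            "version": "test",
            "patterns": [{"smarts": s, "kind": k} for s, k in records],
        }))
        return path

    return _write
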