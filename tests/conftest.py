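from __future__ import annotations

import pytest
from hypothesis import settings

from immucast.rule_model import load_rulebase, packaged_rulebase_path

# reproducible property tests: same examples on every run
settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def rb():
    """The packaged rulebase, loaded once per session."""
    return load_rulebase(packaged_rulebase_path())
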