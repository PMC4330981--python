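import pytest

from aitcea import default_config, run_all_arms


@pytest.fixture(scope="session")
def base_config():
    """The shipped base-case configuration (session-scoped; do not mutate —
    use ``base_config.copy_deep()`` in tests that change parameters)."""
    return default_config()


@pytest.fixture(scope="session")
def base_results(base_config):
    """Deterministic base-case run of all three arms."""
    return run_all_arms(base_config)
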