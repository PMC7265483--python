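import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=150)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from antlerevo import load_registry

    return load_registry()


@pytest.fixture(scope="session")
def fitted(registry):
    from antlerevo import AntlerCharacterModel

    return AntlerCharacterModel.from_registry(registry).fit()
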