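import pytest

from biomotion.kinematics import action_preset, generate_action


@pytest.fixture(scope="session")
def walk_seq():
    """A translating (non-cyclic) 20-frame walking sequence."""
    return generate_action(action_preset("walk"), seed=7)


@pytest.fixture(scope="session")
def jump_seq():
    """A stationary cyclic jumping sequence."""
    return generate_action(action_preset("jump"), seed=7)
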