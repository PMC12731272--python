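import pytest

from cotox import fixture
from cotox.model import GenerationParams, random_model


@pytest.fixture(scope="session")
def fig1():
    return fixture("fig1")


@pytest.fixture(scope="session")
def bars():
    return {name: fixture(name) for name in ("bars_a", "bars_b", "bars_c")}


def make_random_model(seed, S=6, M=5, T=2, **kw):
    return random_model(GenerationParams(S=S, M=M, T=T, seed=seed, **kw))


def f(*labels):
    """Shorthand frozenset constructor: f('a','b') or f('ab')."""
    if len(labels) == 1 and isinstance(labels[0], str) and len(labels[0]) > 1:
        return frozenset(labels[0])
    return frozenset(labels)
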