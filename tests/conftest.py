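import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aoacorpus.chat_io import ChatSession
from aoacorpus.synthetic import WorldParams, simulate_corpus, simulate_world

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


CHAT_FIXTURE = """\
@UTF8
@Begin
@Languages:\teng
@Participants:\tCHI Anne Target_Child , MOT Gail Mother
@ID:\teng|manchester|CHI|2;0.15|female|||Target_Child|||
@ID:\teng|manchester|MOT|||||Mother|||
*CHI:\tball .
%mor:\tn|ball .
*MOT:\tdog and cat .
*CHI:\txxx &-um ball [!] .
*CHI:\tDoggy@c choo+choo .
\tmore juice .
*MOT:\televen .
@End
"""


@pytest.fixture(scope="session")
def chat_text():
    return CHAT_FIXTURE


def make_sessions(spec):
    """Build ChatSessions from {child: [(age, words), ...]}."""
    out = {}
    for child, sess in spec.items():
        out[child] = [
            ChatSession(child, i + 1, age, frozenset(words))
            for i, (age, words) in enumerate(sess)
        ]
    return out


@pytest.fixture(scope="session")
def small_world():
    """A down-scaled synthetic world shared by fast tests."""
    params = WorldParams(n_children=6, n_sessions=18, n_words=120, seed=7)
    return simulate_world(params)


@pytest.fixture(scope="session")
def small_corpus(small_world):
    return simulate_corpus(small_world)


@pytest.fixture(scope="session")
def default_world():
    """The default 12-child study-design world."""
    return simulate_world(WorldParams(seed=11))
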