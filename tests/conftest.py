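import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from equivnet.clip_network import AgentParams, ClipSpace, RelationKind

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return AgentParams()


def build_linear_space(
    members=("A1", "B1", "C1", "D1", "E1"), h=40.0, mirrors=True, extra=()
) -> ClipSpace:
    """A clip space with a linearly trained chain A-B-C-... at strength h."""
    space = ClipSpace()
    for label in list(members) + list(extra):
        space.ensure_clip(label)
    for s, t in zip(members[:-1], members[1:]):
        space.set_h(s, t, h, kind=RelationKind.BASELINE)
        if mirrors:
            space.set_h(t, s, h, kind=RelationKind.SYMMETRY_TRAINED)
    return space


@pytest.fixture
def linear_space():
    return build_linear_space()


@pytest.fixture
def two_class_block_space():
    """Two noiseless linear classes with no inter-class edges."""
    space = build_linear_space(("A1", "B1", "C1"))
    for s, t in (("A2", "B2"), ("B2", "C2")):
        space.ensure_clip(s)
        space.ensure_clip(t)
    for s, t in (("A2", "B2"), ("B2", "C2")):
        space.set_h(s, t, 40.0, kind=RelationKind.BASELINE)
        space.set_h(t, s, 40.0, kind=RelationKind.SYMMETRY_TRAINED)
    return space
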