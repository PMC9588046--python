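import warnings

import numpy as np
import pytest

from contextchoice import choice_sets as cs
from contextchoice.rating_state import RatingState
from contextchoice.synthetic_world import (
    WorldConfig,
    generate_world,
    simulate_choice_stream,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def tiny_config(**overrides) -> WorldConfig:
    """A small world that runs in well under a second."""
    defaults = dict(
        clusters_per_city=12,
        n_users=30,
        events_per_user=40,
        init_reviews_range=(5, 30),
        seed=42,
    )
    defaults.update(overrides)
    return WorldConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(tiny_config())


@pytest.fixture(scope="session")
def tiny_stream(tiny_world):
    records, reviews = simulate_choice_stream(tiny_world, tiny_world.config)
    return records, reviews


@pytest.fixture(scope="session")
def tiny_state(tiny_world, tiny_stream):
    _, reviews = tiny_stream
    return RatingState(
        tiny_world.init_reviews + reviews,
        {r.id: r.price for r in tiny_world.restaurants},
    )


@pytest.fixture(scope="session")
def tiny_sets(tiny_world):
    return [
        cs.ChoiceSetDefinition(set_id=k, member_ids=tuple(sorted(v)))
        for k, v in sorted(tiny_world.true_sets().items())
    ]
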