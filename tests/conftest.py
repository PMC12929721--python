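"""Shared fixtures: small named structures, parameter defaults, sequences."""
from __future__ import annotations

import numpy as np
import pytest

from socstruct import (
    Interaction,
    InteractionSequence,
    SocialStructure,
    SociologyParams,
)


@pytest.fixture(scope="session")
def params() -> SociologyParams:
    return SociologyParams()


@pytest.fixture
def agents3() -> tuple[str, ...]:
    return ("a", "b", "c")


@pytest.fixture
def agents5() -> tuple[str, ...]:
    return ("Pink", "Blue", "Yellow", "Green", "Grey")


@pytest.fixture
def chain3() -> SocialStructure:
    """Three singleton clusters in an authority chain a -> b -> c."""
    return SocialStructure(
        ("a", "b", "c"),
        (("a",), ("b",), ("c",)),
        frozenset({("authority", 0, 1), ("authority", 1, 2)}),
    )


@pytest.fixture
def boss_structure() -> SocialStructure:
    """One boss over a two-agent cluster: X={a} -> Y={b, c}."""
    return SocialStructure(
        ("a", "b", "c"),
        (("a",), ("b", "c")),
        frozenset({("authority", 0, 1)}),
    )


@pytest.fixture
def mentor_structure() -> SocialStructure:
    """Mentorship M={a} -> N={b, c}: a mentors the peer pair b, c."""
    return SocialStructure(
        ("a", "b", "c"),
        (("a",), ("b", "c")),
        frozenset({("mentorship", 0, 1)}),
    )


@pytest.fixture
def two_cliques() -> SocialStructure:
    return SocialStructure(
        ("a", "b", "c", "d"),
        (("a", "b"), ("c", "d")),
        frozenset({("friendship", 0, 0), ("friendship", 1, 1)}),
    )


def make_sequence(agents, *events) -> InteractionSequence:
    """events as (type, initiator, recipient, response) tuples."""
    return InteractionSequence(
        interactions=tuple(Interaction(*e) for e in events),
        agents=tuple(agents),
    )


@pytest.fixture
def orders_ab(agents3) -> InteractionSequence:
    """Two accepted orders a -> b over three agents."""
    return make_sequence(
        agents3,
        ("order", "a", "b", "accept"),
        ("order", "a", "b", "accept"),
    )


@pytest.fixture
def fig_delegation_sequence(agents5) -> InteractionSequence:
    """Pink and Blue both order Yellow; Yellow orders Green and Grey (all accepted)."""
    return make_sequence(
        agents5,
        ("order", "Pink", "Yellow", "accept"),
        ("order", "Pink", "Yellow", "accept"),
        ("order", "Blue", "Yellow", "accept"),
        ("order", "Blue", "Yellow", "accept"),
        ("order", "Yellow", "Green", "accept"),
        ("order", "Yellow", "Green", "accept"),
        ("order", "Yellow", "Grey", "accept"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
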