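"""Three-stage interaction models: normalization, limits, orderings, MLE."""
from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

import socstruct as ss
from socstruct.sociology import FittingError, fit_parameters_mle
from tests.conftest import make_sequence

ALL_TYPES = ("authority", "friendship", "mentorship")


# ---------------------------------------------------------------------------
# Stage distributions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rtype", ALL_TYPES)
def test_stage_distributions_normalize_over_enumerated_structures(rtype, params):
    for s in ss.enumerate_structures(("a", "b", "c"), (rtype,)):
        tab = ss.stage_distributions(s, rtype, params)
        assert sum(tab.initiator.values()) == pytest.approx(1.0, abs=1e-12)
        for i in s.agents:
            assert sum(tab.recipient[i].values()) == pytest.approx(1.0, abs=1e-12)
            for j in s.agents:
                if i != j:
                    assert 0.0 < tab.accept[(i, j)] < 1.0


def test_boss_initiator_distribution(boss_structure, params):
    tab = ss.stage_distributions(boss_structure, "authority", params)
    assert tab.initiator["a"] == pytest.approx(0.6)
    assert tab.initiator["b"] == pytest.approx(0.2)
    assert tab.initiator["c"] == pytest.approx(0.2)
    assert tab.recipient["a"]["b"] == pytest.approx(0.5)
    assert tab.recipient["a"]["c"] == pytest.approx(0.5)


def test_strict_hierarchy_zeroes_indirect_orders(chain3):
    """As beta_down -> 1 orders only go to direct subordinates."""
    strict = ss.SociologyParams(
        authority=ss.AuthorityParams(beta_down=1 - 1e-12)
    )
    tab = ss.stage_distributions(chain3, "authority", strict)
    assert tab.recipient["a"]["c"] < 1e-9
    assert tab.recipient["a"]["b"] > 0.8


def test_clique_blind_boundary_gives_uniform_recipients(two_cliques):
    flat = ss.SociologyParams(
        friendship=ss.FriendshipParams(beta_high=0.5, beta_low=0.5)
    )
    tab = ss.stage_distributions(two_cliques, "friendship", flat)
    for i in two_cliques.agents:
        for p in tab.recipient[i].values():
            assert p == pytest.approx(1 / 3)


def test_same_clique_recipients_preferred(two_cliques, params):
    tab = ss.stage_distributions(two_cliques, "friendship", params)
    assert tab.recipient["a"]["b"] > tab.recipient["a"]["c"]
    assert tab.accept[("a", "b")] > tab.accept[("a", "c")]


def test_mentorship_initiator_ordering(mentor_structure, params):
    """Mentees (b, c) ask; the mentor (a) initiates least."""
    tab = ss.stage_distributions(mentor_structure, "mentorship", params)
    assert tab.initiator["b"] == tab.initiator["c"] > tab.initiator["a"]


def test_mentorship_recipient_prefers_mentor_then_peer(mentor_structure, params):
    tab = ss.stage_distributions(mentor_structure, "mentorship", params)
    # b's options: mentor a (beta_recip) vs peer c (1 - beta_recip)
    assert tab.recipient["b"]["a"] == pytest.approx(0.7)
    assert tab.recipient["b"]["c"] == pytest.approx(0.3)
    # requests up or lateral are cheap to accept; downward ones are not
    assert tab.accept[("b", "a")] == pytest.approx(0.8)
    assert tab.accept[("a", "b")] == pytest.approx(0.2)


def test_authority_initiator_monotone_in_subordinates(params):
    agents = ("a", "b", "c")
    flat = ss.SocialStructure(agents, (("a",), ("b",), ("c",)), frozenset())
    one_sub = ss.SocialStructure(
        agents, (("a",), ("b",), ("c",)), frozenset({("authority", 0, 1)})
    )
    p_flat = ss.stage_distributions(flat, "authority", params).initiator["a"]
    p_sub = ss.stage_distributions(one_sub, "authority", params).initiator["a"]
    assert p_sub > p_flat


def test_superior_orders_accepted_more_often(chain3, params):
    tab = ss.stage_distributions(chain3, "authority", params)
    assert tab.accept[("a", "b")] > tab.accept[("b", "a")]
    assert tab.accept[("a", "c")] > tab.accept[("c", "a")]  # transitive superiority


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_single_order_likelihood_closed_form(params):
    """X={a} -> Y={b}: init 2/3 (weights 2:1), recipient 1, accept beta_pos."""
    s = ss.SocialStructure(("a", "b"), (("a",), ("b",)), frozenset({("authority", 0, 1)}))
    d = ss.Interaction("order", "a", "b", "accept")
    assert math.exp(ss.interaction_log_likelihood(d, s, params)) == pytest.approx(
        (2 / 3) * 1.0 * 0.8
    )
    rej = ss.Interaction("order", "a", "b", "reject")
    assert math.exp(ss.interaction_log_likelihood(rej, s, params)) == pytest.approx(
        (2 / 3) * 1.0 * 0.2
    )


def test_each_type_block_of_outcomes_sums_to_one(params):
    """For a 5-agent structure with all three edge types, the 40 outcomes of
    each type (20 pairs x 2 responses) form a probability distribution."""
    agents = ("p", "q", "r", "s", "t")
    s = ss.SocialStructure(
        agents,
        (("p",), ("q", "r"), ("s", "t")),
        frozenset(
            {("authority", 0, 1), ("mentorship", 2, 1), ("friendship", 1, 1)}
        ),
    )
    for label in ("order", "invite", "request"):
        total = sum(
            math.exp(
                ss.interaction_log_likelihood(
                    ss.Interaction(label, i, j, resp), s, params
                )
            )
            for i, j in itertools.permutations(agents, 2)
            for resp in ("accept", "reject")
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_sequence_likelihood_order_invariant(chain3, params):
    seq = make_sequence(
        chain3.agents,
        ("order", "a", "b", "accept"),
        ("order", "b", "c", "reject"),
        ("order", "a", "c", "accept"),
    )
    permuted = ss.InteractionSequence(
        tuple(reversed(seq.interactions)), seq.agents
    )
    assert ss.sequence_log_likelihood(seq, chain3, params) == pytest.approx(
        ss.sequence_log_likelihood(permuted, chain3, params)
    )


def test_duplicating_interaction_doubles_contribution(chain3, params):
    once = make_sequence(chain3.agents, ("order", "a", "b", "accept"))
    twice = make_sequence(
        chain3.agents, ("order", "a", "b", "accept"), ("order", "a", "b", "accept")
    )
    assert ss.sequence_log_likelihood(twice, chain3, params) == pytest.approx(
        2 * ss.sequence_log_likelihood(once, chain3, params)
    )


def test_empty_sequence_log_likelihood_is_zero(chain3, params):
    empty = ss.InteractionSequence((), chain3.agents)
    assert ss.sequence_log_likelihood(empty, chain3, params) == 0.0


def test_likelihood_invariant_under_cluster_relabeling(params):
    from tests.test_structures import permute_clusters

    s = ss.SocialStructure(
        ("a", "b", "c", "d"),
        (("a", "b"), ("c",), ("d",)),
        frozenset({("authority", 1, 0), ("authority", 1, 2), ("friendship", 0, 0)}),
    )
    seq = make_sequence(
        s.agents,
        ("order", "c", "a", "accept"),
        ("invite", "a", "b", "accept"),
        ("order", "d", "c", "reject"),
    )
    for perm in itertools.permutations(range(3)):
        permuted = permute_clusters(s, perm)
        assert ss.sequence_log_likelihood(seq, permuted, params) == pytest.approx(
            ss.sequence_log_likelihood(seq, s, params)
        )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def test_sampled_frequencies_match_stage_tables(boss_structure, params, rng):
    n = 20_000
    tab = ss.stage_distributions(boss_structure, "authority", params)
    init_counts = {a: 0 for a in boss_structure.agents}
    for _ in range(n):
        d = ss.sample_interaction(boss_structure, "authority", params, rng)
        init_counts[d.initiator] += 1
    for a, p in tab.initiator.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(init_counts[a] / n - p) < 3.5 * se


def test_high_social_cost_means_orders_obeyed(rng):
    costly = ss.SociologyParams(authority=ss.AuthorityParams(beta_pos=0.999))
    s = ss.SocialStructure(
        ("a", "b", "c"), (("a",), ("b", "c")), frozenset({("authority", 0, 1)})
    )
    downward = [
        d
        for d in (ss.sample_interaction(s, "authority", costly, rng) for _ in range(3000))
        if d.initiator == "a"
    ]
    accepted = sum(d.response == "accept" for d in downward)
    assert accepted / len(downward) >= 0.99


def test_sampling_reproducible(boss_structure, params):
    a = ss.sample_sequence(boss_structure, "authority", 10, params, seed=7)
    b = ss.sample_sequence(boss_structure, "authority", 10, params, seed=7)
    assert a == b


def test_sample_requires_two_agents(params):
    s = ss.SocialStructure(("a",), (("a",),), frozenset())
    with pytest.raises(ValueError):
        ss.sample_interaction(s, "authority", params, seed=0)


# ---------------------------------------------------------------------------
# MLE fitting
# ---------------------------------------------------------------------------

def test_mle_recovers_generating_strictness(chain3, params):
    true = ss.SociologyParams(authority=ss.AuthorityParams(beta_down=0.8))
    seq = ss.sample_sequence(chain3, "authority", 200, true, seed=11)
    fit = fit_parameters_mle(
        [(chain3, seq)], "authority", {"beta_down": [0.2, 0.5, 0.8]}
    )
    assert fit.params.authority.beta_down == 0.8
    assert len(fit.trace) == 3


def test_mle_single_observation_no_crash(chain3):
    seq = make_sequence(chain3.agents, ("order", "a", "b", "accept"))
    fit = fit_parameters_mle([(chain3, seq)], "authority", {"beta_down": [0.1, 0.9]})
    assert fit.params.authority.beta_down in (0.1, 0.9)


def test_mle_invariant_to_duplicated_training_data(chain3):
    seq = ss.sample_sequence(chain3, "authority", 50, ss.SociologyParams(), seed=5)
    grid = {"beta_down": [0.3, 0.6, 0.9]}
    once = fit_parameters_mle([(chain3, seq)], "authority", grid)
    twice = fit_parameters_mle([(chain3, seq)] * 2, "authority", grid)
    assert once.params == twice.params
    assert twice.log_likelihood == pytest.approx(2 * once.log_likelihood)


def test_mle_empty_training_rejected():
    with pytest.raises(ValueError):
        fit_parameters_mle([], "authority", {"beta_down": [0.5]})


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cls, kwargs",
    [
        (ss.AuthorityParams, {"beta_down": 0.0}),
        (ss.AuthorityParams, {"eps_lat": 0.0}),
        (ss.FriendshipParams, {"beta_high": 0.1, "beta_low": 0.5}),
        (ss.MentorshipParams, {"dist_discount": 1.5}),
    ],
)
def test_parameter_range_validation(cls, kwargs):
    with pytest.raises(ValueError):
        cls(**kwargs)
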