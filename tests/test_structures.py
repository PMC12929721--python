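"""Structure representation: canonicalization, validity, features, enumeration."""
from __future__ import annotations

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import socstruct as ss
from socstruct.structures import (
    CapacityError,
    StructureValidationError,
    _is_acyclic,
    set_partitions,
)


def permute_clusters(structure: ss.SocialStructure, perm: tuple[int, ...]) -> ss.SocialStructure:
    """Relabel clusters by an index permutation (same abstract structure)."""
    clusters = tuple(structure.clusters[i] for i in perm)
    inv = {old: new for new, old in enumerate(perm)}
    edges = frozenset((t, inv[s], inv[d]) for (t, s, d) in structure.edges)
    return ss.SocialStructure(structure.agents, clusters, edges)


# ---------------------------------------------------------------------------
# canonical_form
# ---------------------------------------------------------------------------

def test_canonical_relabels_by_smallest_member():
    s = ss.SocialStructure(
        ("a", "b"), (("b",), ("a",)), frozenset({("authority", 0, 1)})
    )
    c = ss.canonical_form(s)
    assert c.clusters == (("a",), ("b",))
    assert c.edges == frozenset({("authority", 1, 0)})


def test_canonical_idempotent(chain3):
    once = ss.canonical_form(chain3)
    assert ss.canonical_form(once) == once


@pytest.mark.parametrize("n_types", [1, 2])
def test_all_label_permutations_share_one_canonical_form(n_types):
    """Brute force over every cluster-label permutation of a 5-agent structure."""
    types = [("authority", 0, 1), ("mentorship", 2, 0)][:n_types]
    s = ss.SocialStructure(
        ("v", "w", "x", "y", "z"),
        (("v", "x"), ("w",), ("y", "z")),
        frozenset(types) | frozenset({("friendship", 2, 2)}),
    )
    forms = {
        ss.canonical_form(permute_clusters(s, perm))
        for perm in itertools.permutations(range(3))
    }
    assert len(forms) == 1


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "clusters, edges, fragment",
    [
        ((("a",), ("b",)), {("authority", 0, 1), ("authority", 1, 0)}, "cycle"),
        ((("a",), ("b",)), {("friendship", 0, 1)}, "self-loop"),
        ((("a",), ("b",), ()), set(), "empty"),
        ((("a",), ("a", "b")), set(), "more than one cluster"),
        ((("a",),), set(), "not covered"),
    ],
)
def test_validate_reports_violations(clusters, edges, fragment):
    s = ss.SocialStructure(("a", "b"), clusters, frozenset(edges))
    violations = ss.validate(s)
    assert violations and any(fragment in v for v in violations)


def test_validate_accepts_three_cluster_hierarchy(chain3):
    assert ss.validate(chain3) == []


def test_canonical_rejects_invalid():
    s = ss.SocialStructure(
        ("a", "b"), (("a",), ("b",)),
        frozenset({("authority", 0, 1), ("authority", 1, 0)}),
    )
    with pytest.raises(StructureValidationError, match="cycle"):
        ss.canonical_form(s)


# ---------------------------------------------------------------------------
# agent_features
# ---------------------------------------------------------------------------

def test_chain_features(chain3):
    fa = ss.agent_features(chain3, "a")
    assert fa.n_subordinates == 2
    assert fa.n_superiors == 0
    assert fa.distance_to("c", "authority") == 2
    fc = ss.agent_features(chain3, "c")
    assert fc.n_superiors == 2
    assert fc.distance_to("a", "authority") is None  # no downstream path


def test_single_clique_features():
    agents = tuple("abcde")
    s = ss.SocialStructure(agents, (agents,), frozenset({("friendship", 0, 0)}))
    for a in agents:
        f = ss.agent_features(s, a)
        assert f.clique_size == 5
        assert f.n_subordinates == 0


def test_mentorship_features(mentor_structure):
    fb = ss.agent_features(mentor_structure, "b")
    assert fb.has_mentor and not fb.has_mentee
    assert fb.distance_to("c", "mentorship") == 0  # mutual peers
    fa = ss.agent_features(mentor_structure, "a")
    assert fa.has_mentee and not fa.has_mentor


def test_unknown_agent_raises(chain3):
    with pytest.raises(KeyError):
        ss.agent_features(chain3, "zz")


def test_distances_satisfy_triangle_inequality():
    for s in ss.enumerate_structures(("a", "b", "c", "d"), ("authority",)):
        dist = ss.structures.cluster_distances(s, "authority")
        for i in dist:
            for j in dist[i]:
                for k in dist.get(j, {}):
                    assert dist[i].get(k, 10**9) <= dist[i][j] + dist[j][k]


# ---------------------------------------------------------------------------
# enumerate_structures
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "agents, types, expected",
    [
        (("a", "b"), ("authority",), 4),        # {ab}: 1; {a}{b}: none/->/<-
        (("a", "b", "c"), ("friendship",), 22),  # 2 + 4 + 4 + 4 + 8
        (("a",), ("friendship",), 2),
        (("a",), ("authority",), 1),
    ],
)
def test_enumeration_counts(agents, types, expected):
    structures = ss.enumerate_structures(agents, types)
    assert len(structures) == expected
    assert len(set(structures)) == expected  # all distinct


def test_enumeration_matches_raw_label_bruteforce():
    """Independent oracle: enumerate raw agent->label assignments and raw edge
    tuples, deduplicate by canonical form, and compare counts."""
    agents = ("a", "b", "c")
    found = set()
    for labels in itertools.product(range(3), repeat=3):
        clusters_map: dict[int, list[str]] = {}
        for agent, lab in zip(agents, labels):
            clusters_map.setdefault(lab, []).append(agent)
        clusters = tuple(tuple(c) for c in clusters_map.values())
        k = len(clusters)
        pairs = list(itertools.permutations(range(k), 2))
        for r in range(len(pairs) + 1):
            for combo in itertools.combinations(pairs, r):
                g = nx.DiGraph(combo)
                if not nx.is_directed_acyclic_graph(g):
                    continue
                # at most one edge per unordered pair
                if any((b, a) in combo for (a, b) in combo):
                    continue
                s = ss.SocialStructure(
                    agents, clusters, frozenset(("authority", a, b) for a, b in combo)
                )
                found.add(ss.canonical_form(s))
    assert found == set(ss.enumerate_structures(agents, ("authority",)))


def test_enumeration_capacity_guard():
    with pytest.raises(CapacityError, match="Metropolis"):
        ss.enumerate_structures(tuple("abcde"), ("authority",), max_agents=4)


def test_set_partitions_bell_numbers():
    bell = {1: 1, 2: 2, 3: 5, 4: 15, 5: 52}
    for n, b in bell.items():
        assert sum(1 for _ in set_partitions(range(n))) == b


# ---------------------------------------------------------------------------
# relation_holds
# ---------------------------------------------------------------------------

def test_manager_direct_and_asymmetric():
    s = ss.SocialStructure(("a", "b"), (("a",), ("b",)), frozenset({("authority", 0, 1)}))
    assert ss.relation_holds(s, "manager_of", "a", "b")
    assert not ss.relation_holds(s, "manager_of", "b", "a")


def test_manager_not_transitive_by_default(chain3):
    assert not ss.relation_holds(chain3, "manager_of", "a", "c")
    assert ss.relation_holds(chain3, "manager_of", "a", "c", transitive=True)


def test_friend_of_symmetric():
    s = ss.SocialStructure(("a", "b"), (("a", "b"),), frozenset({("friendship", 0, 0)}))
    assert ss.relation_holds(s, "friend_of", "a", "b")
    assert ss.relation_holds(s, "friend_of", "b", "a")


def test_relation_requires_distinct_agents(chain3):
    with pytest.raises(ValueError):
        ss.relation_holds(chain3, "manager_of", "a", "a")


@pytest.mark.parametrize("relation", ["manager_of", "mentor_of"])
def test_directed_relations_antisymmetric_and_irreflexive(relation):
    rtype = {"manager_of": "authority", "mentor_of": "mentorship"}[relation]
    for s in ss.enumerate_structures(("a", "b", "c"), (rtype,)):
        for i, j in itertools.permutations(s.agents, 2):
            assert not (
                ss.relation_holds(s, relation, i, j)
                and ss.relation_holds(s, relation, j, i)
            )


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@st.composite
def random_structures(draw):
    n = draw(st.integers(2, 4))
    agents = tuple(f"a{i}" for i in range(n))
    labels = draw(st.lists(st.integers(0, n - 1), min_size=n, max_size=n))
    clusters_map: dict[int, list[str]] = {}
    for agent, lab in zip(agents, labels):
        clusters_map.setdefault(lab, []).append(agent)
    clusters = tuple(tuple(c) for c in clusters_map.values())
    k = len(clusters)
    edges = set()
    for a, b in itertools.combinations(range(k), 2):
        state = draw(st.sampled_from(["none", "fwd", "rev"]))
        if state == "fwd":
            edges.add(("authority", a, b))
        elif state == "rev":
            edges.add(("authority", b, a))
    for c in range(k):
        if draw(st.booleans()):
            edges.add(("friendship", c, c))
    s = ss.SocialStructure(agents, clusters, frozenset(edges))
    if ss.validate(s):  # rare authority cycles: drop authority edges
        s = ss.SocialStructure(
            agents, clusters, frozenset(e for e in edges if e[0] == "friendship")
        )
    return s


@settings(derandomize=True, max_examples=60)
@given(random_structures(), st.randoms(use_true_random=False))
def test_canonical_is_permutation_invariant(s, rnd):
    perm = list(range(s.n_clusters))
    rnd.shuffle(perm)
    assert ss.canonical_form(permute_clusters(s, tuple(perm))) == ss.canonical_form(s)


def test_is_acyclic_agrees_with_networkx(rng):
    for _ in range(200):
        n = int(rng.integers(2, 6))
        edges = [
            (int(a), int(b))
            for a, b in rng.integers(0, n, size=(int(rng.integers(0, 8)), 2))
            if a != b
        ]
        assert _is_acyclic(n, edges) == nx.is_directed_acyclic_graph(nx.DiGraph([(a, b) for a, b in edges]) if edges else nx.DiGraph())
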