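"""Latent social structures: agent partitions plus typed inter-cluster edges.

A social structure is a partition of a fixed, ordered set of agents into
clusters (roles/subgroups), together with a set of typed edges between
clusters.  Directed edge types (``authority``, ``mentorship``) encode
hierarchies and must be acyclic; the ``friendship`` type is encoded purely as
cluster self-loops marking cliques.  Agents sharing a cluster are peers for
every relation type (distance 0, no within-cluster directed relations).

This module provides validation, canonicalization (the quotient under
cluster relabeling, needed to aggregate MCMC samples), derived per-agent
graph features used by the interaction models, exhaustive enumeration of all
canonical structures at small agent counts (the exact-inference oracle), and
pairwise relation queries (``manager_of``/``friend_of``/``mentor_of``).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger("socstruct.structures")

AUTHORITY = "authority"
FRIENDSHIP = "friendship"
MENTORSHIP = "mentorship"
RELATION_TYPES = (AUTHORITY, FRIENDSHIP, MENTORSHIP)
#: relation types whose edges connect distinct clusters and form a DAG
DIRECTED_TYPES = (AUTHORITY, MENTORSHIP)

#: bijection between relation types and the surface interaction labels
INTERACTION_LABEL = {AUTHORITY: "order", FRIENDSHIP: "invite", MENTORSHIP: "request"}
RELATION_FOR_LABEL = {v: k for k, v in INTERACTION_LABEL.items()}
INTERACTION_LABELS = tuple(INTERACTION_LABEL[t] for t in RELATION_TYPES)

RESPONSES = ("accept", "reject")

#: pairwise relation queries and the edge type each one reads
RELATION_QUERIES = {
    "manager_of": AUTHORITY,
    "friend_of": FRIENDSHIP,
    "mentor_of": MENTORSHIP,
}

Edge = tuple[str, int, int]  # (relation type, from-cluster index, to-cluster index)


class StructureValidationError(ValueError):
    """Raised when an operation requires a valid structure and gets one that is not."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid social structure: " + "; ".join(self.violations))


class CapacityError(ValueError):
    """Raised when exhaustive enumeration is asked for too many agents."""


@dataclass(frozen=True)
class SocialStructure:
    """A partition of ``agents`` into clusters plus typed inter-cluster edges.

    ``clusters`` is a tuple of agent tuples; ``edges`` holds
    ``(type, from_index, to_index)`` triples indexing into ``clusters``.
    Instances are immutable and hashable so they can key likelihood caches.
    """

    agents: tuple[str, ...]
    clusters: tuple[tuple[str, ...], ...]
    edges: frozenset[Edge]

    @cached_property
    def cluster_of(self) -> Mapping[str, int]:
        return {a: i for i, members in enumerate(self.clusters) for a in members}

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def edges_of(self, rtype: str) -> list[tuple[int, int]]:
        return sorted((s, d) for (t, s, d) in self.edges if t == rtype)

    def has_edge(self, rtype: str, src: int, dst: int) -> bool:
        return (rtype, src, dst) in self.edges

    @cached_property
    def sort_key(self) -> tuple:
        """Deterministic lexicographic key over canonical forms (tie-breaking)."""
        return (self.clusters, tuple(sorted(self.edges)))


def validate(structure: SocialStructure, agents: Sequence[str] | None = None) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    violations: list[str] = []
    agent_list = tuple(agents) if agents is not None else structure.agents
    if len(agent_list) == 0:
        violations.append("agent set is empty")
    if len(set(agent_list)) != len(agent_list):
        violations.append("agent set contains duplicates")

    seen: set[str] = set()
    for idx, members in enumerate(structure.clusters):
        if not members:
            violations.append(f"cluster {idx} is empty")
        for a in members:
            if a in seen:
                violations.append(f"agent {a!r} appears in more than one cluster")
            if a not in agent_list:
                violations.append(f"cluster {idx} contains unknown agent {a!r}")
            seen.add(a)
    missing = set(agent_list) - seen
    if missing:
        violations.append(f"agents not covered by any cluster: {sorted(missing)}")

    k = len(structure.clusters)
    for t, s, d in sorted(structure.edges):
        if t not in RELATION_TYPES:
            violations.append(f"unknown edge type {t!r}")
            continue
        if not (0 <= s < k and 0 <= d < k):
            violations.append(f"edge {t} {s}->{d} references a nonexistent cluster")
            continue
        if t == FRIENDSHIP and s != d:
            violations.append(
                f"friendship edge {s}->{d} must be a self-loop (cliques only)"
            )
        if t in DIRECTED_TYPES and s == d:
            violations.append(f"{t} edge {s}->{s} is a self-loop on a single cluster")
    for t in DIRECTED_TYPES:
        pairs = [(s, d) for (s, d) in _edge_pairs(structure, t) if s != d]
        if not _is_acyclic(k, pairs):
            violations.append(f"{t} edges contain a cycle")
    return violations


def _edge_pairs(structure: SocialStructure, rtype: str) -> list[tuple[int, int]]:
    return [(s, d) for (t, s, d) in structure.edges if t == rtype]


def _is_acyclic(n_nodes: int, edges: Sequence[tuple[int, int]]) -> bool:
    # Iterative DFS three-coloring; cluster graphs never exceed ~10 nodes.
    succ: dict[int, list[int]] = {}
    for s, d in edges:
        succ.setdefault(s, []).append(d)
    color = [0] * n_nodes  # 0 white, 1 grey, 2 black
    for root in succ:
        if color[root]:
            continue
        stack: list[tuple[int, int]] = [(root, 0)]
        color[root] = 1
        while stack:
            node, i = stack[-1]
            children = succ.get(node, ())
            if i < len(children):
                stack[-1] = (node, i + 1)
                child = children[i]
                if color[child] == 1:
                    return False
                if color[child] == 0:
                    color[child] = 1
                    stack.append((child, 0))
            else:
                color[node] = 2
                stack.pop()
    return True


def require_valid(structure: SocialStructure) -> None:
    violations = validate(structure)
    if violations:
        raise StructureValidationError(violations)


def canonical_form(structure: SocialStructure) -> SocialStructure:
    """Relabel clusters into the canonical order (by smallest member, in agent order).

    Two structures identical up to cluster relabeling map to the same canonical
    form; the map is idempotent.  Members within a cluster are sorted by agent
    order as well, so canonical structures compare and hash consistently.
    """
    require_valid(structure)
    pos = {a: i for i, a in enumerate(structure.agents)}
    sorted_clusters = [tuple(sorted(c, key=pos.__getitem__)) for c in structure.clusters]
    order = sorted(range(len(sorted_clusters)), key=lambda i: pos[sorted_clusters[i][0]])
    remap = {old: new for new, old in enumerate(order)}
    clusters = tuple(sorted_clusters[i] for i in order)
    edges = frozenset((t, remap[s], remap[d]) for (t, s, d) in structure.edges)
    return SocialStructure(tuple(structure.agents), clusters, edges)


def cluster_graph(structure: SocialStructure, rtype: str) -> nx.DiGraph:
    """The directed cluster graph for one relation type (friendship loops included)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(structure.n_clusters))
    g.add_edges_from(_edge_pairs(structure, rtype))
    return g


def cluster_distances(structure: SocialStructure, rtype: str) -> dict[int, dict[int, int]]:
    """All-pairs directed shortest path lengths between clusters (per type).

    ``dist[i][j]`` is present iff ``j`` is reachable from ``i``; ``dist[i][i] == 0``.
    """
    g = cluster_graph(structure, rtype)
    return {src: dict(lengths) for src, lengths in nx.all_pairs_shortest_path_length(g)}


@dataclass(frozen=True)
class AgentFeatures:
    """Structure-derived features of one agent, as read by the interaction models."""

    agent: str
    cluster: int
    n_subordinates: int
    n_superiors: int
    clique_size: int
    has_mentor: bool
    has_mentee: bool
    _cluster_of: Mapping[str, int]
    _distances: Mapping[str, Mapping[int, Mapping[int, int]]]

    def distance_to(self, other: str, rtype: str) -> int | None:
        """Directed cluster-graph distance to ``other`` (0 within a cluster, None if no path)."""
        cj = self._cluster_of[other]
        return self._distances[rtype].get(self.cluster, {}).get(cj)


def agent_features(structure: SocialStructure, agent: str) -> AgentFeatures:
    require_valid(structure)
    if agent not in structure.cluster_of:
        raise KeyError(f"unknown agent {agent!r}")
    ci = structure.cluster_of[agent]
    sizes = [len(c) for c in structure.clusters]

    g_auth = cluster_graph(structure, AUTHORITY)
    n_sub = sum(sizes[c] for c in nx.descendants(g_auth, ci))
    n_sup = sum(sizes[c] for c in nx.ancestors(g_auth, ci))

    clique = sizes[ci] if structure.has_edge(FRIENDSHIP, ci, ci) else 0
    has_mentor = any(t == MENTORSHIP and d == ci for (t, s, d) in structure.edges)
    has_mentee = any(t == MENTORSHIP and s == ci for (t, s, d) in structure.edges)

    distances = {t: cluster_distances(structure, t) for t in DIRECTED_TYPES}
    return AgentFeatures(
        agent=agent,
        cluster=ci,
        n_subordinates=n_sub,
        n_superiors=n_sup,
        clique_size=clique,
        has_mentor=has_mentor,
        has_mentee=has_mentee,
        _cluster_of=structure.cluster_of,
        _distances=distances,
    )


def relation_holds(
    structure: SocialStructure,
    relation: str,
    i: str,
    j: str,
    transitive: bool = False,
) -> bool:
    """Whether agent ``i`` stands in ``relation`` to agent ``j`` under ``structure``.

    ``manager_of`` and ``mentor_of`` read a *direct* inter-cluster edge by
    default (``transitive=True`` accepts any directed path); ``friend_of``
    means sharing a cluster that carries a friendship self-loop.
    """
    if i == j:
        raise ValueError("relation queries require two distinct agents")
    if relation not in RELATION_QUERIES:
        raise ValueError(f"unknown relation {relation!r}")
    require_valid(structure)
    ci, cj = structure.cluster_of[i], structure.cluster_of[j]
    rtype = RELATION_QUERIES[relation]
    if relation == "friend_of":
        return ci == cj and structure.has_edge(FRIENDSHIP, ci, ci)
    if ci == cj:
        return False
    if transitive:
        return cj in nx.descendants(cluster_graph(structure, rtype), ci)
    return structure.has_edge(rtype, ci, cj)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (exact-inference oracle at small agent counts)
# ---------------------------------------------------------------------------

def set_partitions(items: Sequence) -> Iterator[list[tuple]]:
    """All set partitions of ``items``, clusters ordered by first occurrence."""
    items = list(items)
    n = len(items)

    def rec(i: int, groups: list[list]):
        if i == n:
            yield [tuple(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    if n == 0:
        return
    yield from rec(0, [])


def _directed_edge_configs(k: int) -> list[frozenset[tuple[int, int]]]:
    """All acyclic orientations-with-absence over unordered cluster pairs."""
    pairs = list(itertools.combinations(range(k), 2))
    configs = []
    for states in itertools.product((None, 0, 1), repeat=len(pairs)):
        edges = []
        for (a, b), st in zip(pairs, states):
            if st == 0:
                edges.append((a, b))
            elif st == 1:
                edges.append((b, a))
        if _is_acyclic(k, edges):
            configs.append(frozenset(edges))
    return configs


def enumerate_structures(
    agents: Sequence[str],
    types: Sequence[str],
    max_agents: int = 4,
) -> list[SocialStructure]:
    """Exactly one canonical structure per equivalence class, exhaustively.

    Covers every set partition of ``agents`` and, per partition, every valid
    typed-edge configuration (acyclic for directed types, arbitrary self-loop
    subsets for friendship).  Guarded by ``max_agents``: the space grows
    super-exponentially and large agent sets should use the MH sampler.
    """
    agents = tuple(agents)
    if len(agents) > max_agents:
        raise CapacityError(
            f"exhaustive enumeration over {len(agents)} agents exceeds the "
            f"max_agents={max_agents} limit; use the Metropolis-Hastings sampler"
        )
    types = tuple(types)
    unknown = set(types) - set(RELATION_TYPES)
    if unknown:
        raise ValueError(f"unknown relation types {sorted(unknown)}")

    out: list[SocialStructure] = []
    directed_cache: dict[int, list[frozenset[tuple[int, int]]]] = {}
    for partition in set_partitions(agents):
        k = len(partition)
        per_type: list[list[frozenset[Edge]]] = []
        for t in types:
            if t == FRIENDSHIP:
                configs = [
                    frozenset((FRIENDSHIP, c, c) for c in loops)
                    for r in range(k + 1)
                    for loops in itertools.combinations(range(k), r)
                ]
            else:
                if k not in directed_cache:
                    directed_cache[k] = _directed_edge_configs(k)
                configs = [
                    frozenset((t, s, d) for (s, d) in cfg) for cfg in directed_cache[k]
                ]
            per_type.append(configs)
        clusters = tuple(partition)
        for combo in itertools.product(*per_type) if per_type else [()]:
            edges = frozenset().union(*combo) if combo else frozenset()
            out.append(SocialStructure(agents, clusters, edges))
    return out
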