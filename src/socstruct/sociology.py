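"""Naive-sociology generative models of typed dyadic interactions.

Each interaction ``d = (type, initiator, recipient, response)`` is modeled in
three stages given a latent structure S:

    P(d | S) = P_t(init | S) * P_t(recip | init, S) * P_t(response | init, recip, S)

with one model per relation type.  Intuitively: orders originate from agents
with many subordinates and flow down the authority hierarchy, preferring
nearby subordinates, and are costly to refuse when they come from a superior;
invitations originate from agents in larger cliques and stay (and succeed)
within the clique; advice requests originate from agents who have mentors but
no mentees and flow up the mentorship hierarchy or laterally to peers.

The concrete functional forms (documented per stage below) are this
package's canonical instantiation of those qualitative constraints; they are
isolated behind :func:`stage_distributions` so alternative parameterizations
can be swapped in without touching inference.  Interactions are conditionally
independent given S, so sequence log-likelihoods are sums.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .structures import (
    AUTHORITY,
    FRIENDSHIP,
    INTERACTION_LABEL,
    MENTORSHIP,
    RELATION_FOR_LABEL,
    RESPONSES,
    SocialStructure,
    cluster_distances,
    require_valid,
)

logger = logging.getLogger("socstruct.sociology")


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """One typed dyadic event: (interaction label, initiator, recipient, response)."""

    type: str
    initiator: str
    recipient: str
    response: str

    def __post_init__(self):
        if self.type not in RELATION_FOR_LABEL:
            raise ValueError(f"unknown interaction type {self.type!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.initiator == self.recipient:
            raise ValueError("initiator and recipient must differ")


@dataclass(frozen=True)
class InteractionSequence:
    """An ordered sequence of interactions over a fixed agent set."""

    interactions: tuple[Interaction, ...]
    agents: tuple[str, ...]

    def __post_init__(self):
        known = set(self.agents)
        for d in self.interactions:
            if d.initiator not in known or d.recipient not in known:
                raise ValueError(
                    f"interaction {d} involves agents outside {self.agents}"
                )

    def __len__(self) -> int:
        return len(self.interactions)

    @property
    def types_present(self) -> tuple[str, ...]:
        return tuple(sorted({d.type for d in self.interactions}))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuthorityParams:
    """Authority/orders parameters.

    ``beta_down``/``beta_up`` control hierarchy strictness (near 1: orders go
    only one step down/up), ``beta_pos`` the social cost of refusing a
    superior, and ``eps_up``/``eps_lat`` the baseline weights for upward and
    peer/unrelated recipients (upward orders are unlikely but possible).
    """

    beta_down: float = 0.8
    beta_up: float = 0.9
    beta_pos: float = 0.8
    eps_up: float = 0.1
    eps_lat: float = 0.1

    def __post_init__(self):
        for name in ("beta_down", "beta_up", "beta_pos"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("eps_up", "eps_lat"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FriendshipParams:
    """Friendship/invitations parameters.

    ``beta_init`` discounts how strongly larger cliques drive initiation;
    ``beta_high > beta_low`` set the cliquishness (within- vs cross-clique
    invitation weight and acceptance odds).  ``beta_high == beta_low`` is the
    degenerate clique-blind boundary and is permitted.
    """

    beta_init: float = 1.0
    beta_high: float = 0.9
    beta_low: float = 0.1

    def __post_init__(self):
        if self.beta_init < 0:
            raise ValueError("beta_init must be nonnegative")
        if not self.beta_low > 0:
            raise ValueError("beta_low must be positive")
        if self.beta_high < self.beta_low:
            raise ValueError("beta_high must be >= beta_low")


@dataclass(frozen=True)
class MentorshipParams:
    """Mentorship/advice-request parameters.

    ``beta_request`` flattens the mentee-over-mentor initiation preference
    (near 1: everyone equally likely to ask); ``beta_recip`` the preference
    for asking mentors over peers; ``beta_pos`` the cost of refusing a mentee
    or peer; ``dist_discount`` the decay per extra hierarchy step toward
    distant mentors; ``eps_m`` the baseline for downstream/unrelated targets.
    """

    beta_request: float = 0.3
    beta_recip: float = 0.7
    beta_pos: float = 0.8
    dist_discount: float = 0.1
    eps_m: float = 0.1

    def __post_init__(self):
        for name in ("beta_request", "beta_recip", "beta_pos", "dist_discount"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.eps_m > 0:
            raise ValueError("eps_m must be positive")


@dataclass(frozen=True)
class SociologyParams:
    authority: AuthorityParams = field(default_factory=AuthorityParams)
    friendship: FriendshipParams = field(default_factory=FriendshipParams)
    mentorship: MentorshipParams = field(default_factory=MentorshipParams)

    def component(self, rtype: str):
        return getattr(self, rtype)


# ---------------------------------------------------------------------------
# Stage distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageTables:
    """Full outcome tables for one structure and one relation type."""

    agents: tuple[str, ...]
    initiator: Mapping[str, float]
    recipient: Mapping[str, Mapping[str, float]]
    accept: Mapping[tuple[str, str], float]


def stage_distributions(
    structure: SocialStructure,
    rtype: str,
    params: SociologyParams,
) -> StageTables:
    """Initiator / recipient / response tables for one sociology on one structure."""
    if rtype not in (AUTHORITY, FRIENDSHIP, MENTORSHIP):
        raise ValueError(f"unsupported relation type {rtype!r}")
    return _stage_tables_cached(structure, rtype, params.component(rtype))


@lru_cache(maxsize=200_000)
def _stage_tables_cached(structure, rtype, comp):
    require_valid(structure)
    agents = structure.agents
    cl = structure.cluster_of
    sizes = [len(c) for c in structure.clusters]
    k = structure.n_clusters

    if rtype == AUTHORITY:
        dist = cluster_distances(structure, AUTHORITY)
        # subordinate counts per cluster (agents strictly downstream)
        n_sub = [
            sum(sizes[j] for j in dist[c] if j != c) for c in range(k)
        ]
        init_w = np.array([1.0 + n_sub[cl[a]] for a in agents])

        def recip_w(i, j):
            ci, cj = cl[i], cl[j]
            if ci == cj:
                return comp.eps_lat
            d = dist[ci].get(cj)
            if d is not None:
                return (1.0 - comp.beta_down) ** (d - 1)
            d = dist[cj].get(ci)
            if d is not None:
                return comp.eps_up * (1.0 - comp.beta_up) ** (d - 1)
            return comp.eps_lat

        def accept_p(i, j):
            # beta_pos when the initiator is strictly upstream of the recipient
            return comp.beta_pos if cl[j] in dist[cl[i]] and cl[i] != cl[j] else 1.0 - comp.beta_pos

    elif rtype == FRIENDSHIP:
        loops = {c for c in range(k) if structure.has_edge(FRIENDSHIP, c, c)}
        clique = [sizes[c] if c in loops else 0 for c in range(k)]
        init_w = np.array(
            [(1.0 + max(clique[cl[a]] - 1, 0)) ** comp.beta_init for a in agents]
        )
        denom = comp.beta_high + comp.beta_low

        def same_clique(i, j):
            return cl[i] == cl[j] and cl[i] in loops

        def recip_w(i, j):
            return comp.beta_high if same_clique(i, j) else comp.beta_low

        def accept_p(i, j):
            return (comp.beta_high if same_clique(i, j) else comp.beta_low) / denom

    else:  # mentorship
        dist = cluster_distances(structure, MENTORSHIP)
        has_mentor = [any(c in dist[s] and s != c for s in range(k)) for c in range(k)]
        has_mentee = [any(t != c for t in dist[c]) for c in range(k)]

        def u(c):
            if has_mentor[c] and not has_mentee[c]:
                return 1.0
            if has_mentee[c] and not has_mentor[c]:
                return 0.0
            return 0.5

        init_w = np.array(
            [comp.beta_request + (1.0 - comp.beta_request) * u(cl[a]) for a in agents]
        )

        def recip_w(i, j):
            ci, cj = cl[i], cl[j]
            if ci == cj:
                return 1.0 - comp.beta_recip
            d = dist[cj].get(ci)  # j upstream of i: j is i's mentor-side ancestor
            if d is not None:
                return comp.beta_recip * comp.dist_discount ** (d - 1)
            return comp.eps_m

        def accept_p(i, j):
            # beta_pos when the request flows up to a mentor or laterally to a peer
            ci, cj = cl[i], cl[j]
            upward_or_peer = ci == cj or (ci in dist[cj])
            return comp.beta_pos if upward_or_peer else 1.0 - comp.beta_pos

    if not np.all(init_w > 0):  # cannot occur with the forms above; guarded anyway
        logger.warning("degenerate initiator weights; falling back to uniform")
        init_w = np.ones(len(agents))
    init_p = dict(zip(agents, init_w / init_w.sum()))

    recipient: dict[str, dict[str, float]] = {}
    accept: dict[tuple[str, str], float] = {}
    for i in agents:
        others = [j for j in agents if j != i]
        w = np.array([recip_w(i, j) for j in others])
        w = w / w.sum()
        recipient[i] = dict(zip(others, w))
        for j in others:
            accept[(i, j)] = accept_p(i, j)
    return StageTables(agents=agents, initiator=init_p, recipient=recipient, accept=accept)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def interaction_log_likelihood(
    d: Interaction,
    structure: SocialStructure,
    params: SociologyParams,
    as_relation: str | None = None,
) -> float:
    """log P(d | S) under the sociology matching d's type (or ``as_relation``).

    ``as_relation`` re-interprets the event under a different sociology (the
    alternate-model analyses), e.g. reading an order as if it were an
    invitation.
    """
    rtype = as_relation or RELATION_FOR_LABEL[d.type]
    tables = stage_distributions(structure, rtype, params)
    p_acc = tables.accept[(d.initiator, d.recipient)]
    p_resp = p_acc if d.response == "accept" else 1.0 - p_acc
    return (
        math.log(tables.initiator[d.initiator])
        + math.log(tables.recipient[d.initiator][d.recipient])
        + math.log(p_resp)
    )


def sequence_log_likelihood(
    D: InteractionSequence,
    structure: SocialStructure,
    params: SociologyParams,
    relation_map: Mapping[str, str] | None = None,
) -> float:
    """log P(D | S): the sum over conditionally independent interactions.

    ``relation_map`` optionally maps interaction labels to the sociology used
    to interpret them (defaults to the canonical label->relation bijection).
    """
    if len(D) == 0:
        logger.info("empty interaction sequence: log-likelihood is 0 (empty product)")
        return 0.0
    total = 0.0
    for d in D.interactions:
        rel = relation_map[d.type] if relation_map else None
        total += interaction_log_likelihood(d, structure, params, as_relation=rel)
    return total


def sample_interaction(
    structure: SocialStructure,
    rtype: str,
    params: SociologyParams,
    seed: int | np.random.Generator | None = None,
) -> Interaction:
    """Ancestral draw through the three stages; reproducible given a seed."""
    if len(structure.agents) < 2:
        raise ValueError("sampling an interaction requires at least 2 agents")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = stage_distributions(structure, rtype, params)
    agents = list(tables.agents)
    i = rng.choice(agents, p=[tables.initiator[a] for a in agents])
    others = [a for a in agents if a != i]
    j = rng.choice(others, p=[tables.recipient[i][a] for a in others])
    resp = "accept" if rng.random() < tables.accept[(i, j)] else "reject"
    return Interaction(type=INTERACTION_LABEL[rtype], initiator=str(i), recipient=str(j), response=resp)


def sample_sequence(
    structure: SocialStructure,
    rtype: str,
    n: int,
    params: SociologyParams,
    seed: int | np.random.Generator | None = None,
) -> InteractionSequence:
    """n independent draws from one structure under one sociology."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = tuple(sample_interaction(structure, rtype, params, rng) for _ in range(n))
    return InteractionSequence(interactions=draws, agents=structure.agents)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

class FittingError(RuntimeError):
    pass


@dataclass
class FitResult:
    params: SociologyParams
    log_likelihood: float
    trace: list[tuple[dict[str, float], float]]


def fit_parameters_mle(
    training: Sequence[tuple[SocialStructure, InteractionSequence]],
    rtype: str,
    search_grid: Mapping[str, Sequence[float]],
    base_params: SociologyParams | None = None,
) -> FitResult:
    """Grid-search MLE of one sociology's parameters on (structure, sequence) pairs.

    Deterministic given the grid; ties broken by first-in-grid order.  Returns
    the full parameter set with the fitted component substituted, plus the
    per-cell log-likelihood trace.
    """
    if not training:
        raise ValueError("training set must be nonempty")
    base = base_params or SociologyParams()
    names = list(search_grid)
    best: tuple[float, SociologyParams] | None = None
    trace: list[tuple[dict[str, float], float]] = []
    for values in product(*(search_grid[n] for n in names)):
        cell = dict(zip(names, values))
        comp = replace(base.component(rtype), **cell)
        candidate = replace(base, **{rtype: comp})
        total = 0.0
        for struct, seq in training:
            total += sequence_log_likelihood(seq, struct, candidate)
            if total == float("-inf"):
                break
        trace.append((cell, total))
        if math.isfinite(total) and (best is None or total > best[0]):
            best = (total, candidate)
    if best is None:
        raise FittingError(
            "every grid cell has log-likelihood -inf; check the grid ranges "
            "against the parameter constraints and the training structures"
        )
    return FitResult(params=best[1], log_likelihood=best[0], trace=trace)
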