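"""Structure prior P(S): a CRP over partitions plus Bernoulli typed-edge priors.

The partition prior is a Chinese Restaurant Process with concentration
``alpha`` (default 3), sampled constructively by stick-breaking and evaluated
in closed form via the exchangeable partition probability function (EPPF)

    P(partition) = alpha^K * prod_k (n_k - 1)! / (alpha * (alpha+1) * ... * (alpha+n-1)).

Conditional on the partition, each unordered pair of distinct clusters
carries, independently per directed relation type, an edge with probability
``edge_prob`` (default 0.5) whose direction is uniform; each cluster carries a
friendship self-loop with probability ``edge_prob``.  Cyclic directed
configurations are rejected (log-prior -inf), so the structure prior is
unnormalized within each partition -- which is all that Metropolis-Hastings
and the enumeration oracle require.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .structures import (
    DIRECTED_TYPES,
    FRIENDSHIP,
    SocialStructure,
    validate,
)

logger = logging.getLogger("socstruct.prior")


@dataclass(frozen=True)
class PriorConfig:
    """CRP concentration, edge-existence probability and stick truncation."""

    alpha: float = 3.0
    edge_prob: float = 0.5
    stick_truncation: int = 50

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.edge_prob < 1:
            raise ValueError("edge_prob must lie strictly between 0 and 1")
        if self.stick_truncation < 1:
            raise ValueError("stick_truncation must be at least 1")


def crp_partition_log_prob(partition: Sequence[Sequence] | Sequence[int], alpha: float) -> float:
    """Log EPPF of a set partition (or of its cluster sizes) under CRP(alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(partition) == 0:
        raise ValueError("partition must be nonempty")
    if isinstance(partition[0], (int, np.integer)):
        sizes = [int(s) for s in partition]
    else:
        sizes = [len(c) for c in partition]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    n = sum(sizes)
    k = len(sizes)
    log_num = k * math.log(alpha) + sum(float(gammaln(s)) for s in sizes)
    log_den = float(gammaln(alpha + n) - gammaln(alpha))
    return log_num - log_den


def sample_partition(
    n_agents: int,
    config: PriorConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[tuple[int, ...], ...]:
    """Draw a partition of ``range(n_agents)`` by truncated stick-breaking.

    Component weights follow GEM(alpha) truncated at ``stick_truncation``;
    agents are assigned independently by weight and empty components dropped.
    Clusters are returned ordered by first member, so the labeling is the
    canonical one.  The truncation error is logged when non-negligible.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be at least 1")
    config = config or PriorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m = config.stick_truncation
    betas = rng.beta(1.0, config.alpha, size=m)
    sticks = np.empty(m)
    remaining = 1.0
    for i in range(m):
        sticks[i] = betas[i] * remaining
        remaining *= 1.0 - betas[i]
    if remaining > 1e-4:
        logger.warning(
            "stick-breaking truncation at %d components leaves %.2e unassigned mass",
            m,
            remaining,
        )
    weights = sticks / sticks.sum()
    labels = rng.choice(m, size=n_agents, p=weights)

    clusters: dict[int, list[int]] = {}
    for agent, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(agent)
    ordered = sorted(clusters.values(), key=lambda c: c[0])
    return tuple(tuple(c) for c in ordered)


def structure_log_prior(
    structure: SocialStructure,
    types: Sequence[str],
    config: PriorConfig | None = None,
) -> float:
    """Unnormalized log prior of a structure: log EPPF + typed-edge terms.

    Directed types contribute ``log(edge_prob * 0.5)`` per present edge
    (existence times uniform direction) and ``log(1 - edge_prob)`` per absent
    unordered cluster pair; friendship contributes ``log(edge_prob)`` /
    ``log(1 - edge_prob)`` per cluster self-loop present/absent.  Invalid
    structures (including cyclic directed configurations) get ``-inf``.
    """
    config = config or PriorConfig()
    violations = validate(structure)
    if violations:
        logger.debug("structure has zero prior mass: %s", "; ".join(violations))
        return float("-inf")

    logp = crp_partition_log_prob(structure.clusters, config.alpha)
    k = structure.n_clusters
    p = config.edge_prob
    n_pairs = k * (k - 1) // 2
    for t in types:
        if t == FRIENDSHIP:
            n_loops = sum(structure.has_edge(FRIENDSHIP, c, c) for c in range(k))
            logp += n_loops * math.log(p) + (k - n_loops) * math.log(1 - p)
        elif t in DIRECTED_TYPES:
            n_edges = len(structure.edges_of(t))
            logp += n_edges * math.log(p * 0.5) + (n_pairs - n_edges) * math.log(1 - p)
        else:
            raise ValueError(f"unknown relation type {t!r}")
    return logp
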