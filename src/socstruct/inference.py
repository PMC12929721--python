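"""Posterior inference P(S | D) over cluster-graph social structures.

Two routes to the same posterior:

* :func:`exhaustive_posterior` — exact normalization of prior x likelihood
  over every canonical structure, feasible only at small agent counts; the
  oracle against which the sampler is validated.
* :func:`mh_posterior` — Metropolis-Hastings over (partition, typed edges).
  Each sweep reassigns every agent (proposal: join an existing cluster with
  probability proportional to its size, or open a new cluster with
  probability proportional to the CRP concentration; a newly opened cluster
  draws its incident edges from the edge prior) and then resamples every
  typed cluster pair / self-loop from the prior's edge states.  Because both
  proposals draw from the prior's own conditionals, the CRP and edge-prior
  factors cancel in the acceptance ratio, which reduces to the likelihood
  ratio; cycle-creating proposals have zero prior mass and are rejected.

Posterior mass is aggregated over canonical forms, so label permutations of
the same structure pool their samples.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .prior import PriorConfig, structure_log_prior
from .sociology import (
    InteractionSequence,
    SociologyParams,
    sequence_log_likelihood,
)
from .structures import (
    DIRECTED_TYPES,
    FRIENDSHIP,
    RELATION_FOR_LABEL,
    SocialStructure,
    _is_acyclic,
    enumerate_structures,
)

logger = logging.getLogger("socstruct.inference")


class InferenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the study's 60000-sample, 5000-burn-in runs."""

    n_samples: int = 60_000
    burn_in: int = 5_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")


@dataclass
class StructurePosterior:
    """A normalized distribution over canonical structures."""

    support: list[SocialStructure]
    probabilities: np.ndarray
    provenance: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.support) != len(self.probabilities):
            raise ValueError("support and probabilities must align")
        total = self.probabilities.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities sum to {total}, not 1")

    def items(self):
        return zip(self.support, self.probabilities)

    def prob_of(self, structure: SocialStructure) -> float:
        for s, p in self.items():
            if s == structure:
                return float(p)
        return 0.0

    def map_structure(self) -> SocialStructure:
        return top_k_structures(self, 1)[0][0]

    def expectation(self, fn: Callable[[SocialStructure], float]) -> float:
        return float(sum(p * fn(s) for s, p in self.items()))


def tv_distance(p: StructurePosterior, q: StructurePosterior) -> float:
    """Total variation distance: half the L1 gap over the union support."""
    pm = {s: float(w) for s, w in p.items()}
    qm = {s: float(w) for s, w in q.items()}
    keys = set(pm) | set(qm)
    return 0.5 * sum(abs(pm.get(s, 0.0) - qm.get(s, 0.0)) for s in keys)


def top_k_structures(
    posterior: StructurePosterior, k: int
) -> list[tuple[SocialStructure, float]]:
    """The k most probable structures, ties broken by canonical lexicographic order."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(posterior.support):
        logger.warning(
            "requested top-%d of a posterior with support %d; returning all",
            k,
            len(posterior.support),
        )
        k = len(posterior.support)
    ranked = sorted(posterior.items(), key=lambda sp: (-sp[1], sp[0].sort_key))
    return [(s, float(p)) for s, p in ranked[:k]]


def exhaustive_posterior(
    D: InteractionSequence,
    types: Sequence[str],
    params: SociologyParams | None = None,
    prior_config: PriorConfig | None = None,
    max_agents: int = 4,
    relation_map: Mapping[str, str] | None = None,
) -> StructurePosterior:
    """Exact posterior by enumerating every canonical structure (small n only)."""
    params = params or SociologyParams()
    prior_config = prior_config or PriorConfig()
    support = enumerate_structures(D.agents, types, max_agents=max_agents)
    logp = np.array(
        [
            structure_log_prior(s, types, prior_config)
            + sequence_log_likelihood(D, s, params, relation_map=relation_map)
            for s in support
        ]
    )
    keep = np.isfinite(logp)
    support = [s for s, ok in zip(support, keep) if ok]
    logp = logp[keep]
    if len(support) == 0:
        raise InferenceError("no structure has positive posterior mass")
    logp -= logp.max()
    w = np.exp(logp)
    return StructurePosterior(
        support=support,
        probabilities=w / w.sum(),
        provenance="exhaustive",
        diagnostics={"n_structures": len(support)},
    )


# ---------------------------------------------------------------------------
# Metropolis-Hastings sampler
# ---------------------------------------------------------------------------

def mh_posterior(
    D: InteractionSequence,
    types: Sequence[str],
    params: SociologyParams | None = None,
    prior_config: PriorConfig | None = None,
    mcmc_config: MCMCConfig | None = None,
    relation_map: Mapping[str, str] | None = None,
) -> StructurePosterior:
    """Approximate P(S | D) by MH over (partition, typed edges).

    An empty ``D`` has log-likelihood identically 0, so the chain then
    targets the prior (used by the detailed-balance diagnostics).
    """
    params = params or SociologyParams()
    prior_config = prior_config or PriorConfig()
    cfg = mcmc_config or MCMCConfig()
    types = tuple(types)
    agents = D.agents
    n = len(agents)
    if len(D) == 0:
        logger.info("empty sequence: MH targets the structure prior")
    rng = np.random.default_rng(cfg.seed)
    alpha = prior_config.alpha
    p_edge = prior_config.edge_prob
    directed = [t for t in types if t in DIRECTED_TYPES]
    has_friend = FRIENDSHIP in types

    # event multiset, for fast likelihood under a new structure
    events = Counter(
        (d.type, d.initiator, d.recipient, d.response) for d in D.interactions
    )
    rel_of = relation_map or RELATION_FOR_LABEL

    # --- mutable chain state ------------------------------------------------
    z = [0] * n                      # agent -> cluster label
    members: dict[int, list[int]] = {0: list(range(n))}
    edges: dict[str, set[tuple[int, int]]] = {t: set() for t in types}
    next_label = 1

    from .sociology import stage_distributions  # local import to avoid cycle at import time

    def build_structure() -> SocialStructure:
        order: dict[int, int] = {}
        for a in range(n):
            if z[a] not in order:
                order[z[a]] = len(order)
        clusters: list[list[str]] = [[] for _ in order]
        for a in range(n):
            clusters[order[z[a]]].append(agents[a])
        e = frozenset(
            (t, order[s], order[d]) for t in types for (s, d) in edges[t]
        )
        return SocialStructure(agents, tuple(tuple(c) for c in clusters), e)

    def state_key() -> tuple:
        order: dict[int, int] = {}
        zc = []
        for a in range(n):
            l = z[a]
            if l not in order:
                order[l] = len(order)
            zc.append(order[l])
        ekey = tuple(
            tuple(sorted((order[s], order[d]) for (s, d) in edges[t])) for t in types
        )
        return (tuple(zc), ekey)

    loglik_cache: dict[tuple, float] = {}
    structures: dict[tuple, SocialStructure] = {}

    def current_loglik() -> float:
        key = state_key()
        hit = loglik_cache.get(key)
        if hit is not None:
            return hit
        struct = build_structure()
        total = 0.0
        tables: dict[str, object] = {}
        for (lab, i, j, resp), c in events.items():
            rt = rel_of[lab]
            tab = tables.get(rt)
            if tab is None:
                tab = stage_distributions(struct, rt, params)
                tables[rt] = tab
            p_acc = tab.accept[(i, j)]
            p = (
                math.log(tab.initiator[i])
                + math.log(tab.recipient[i][j])
                + math.log(p_acc if resp == "accept" else 1.0 - p_acc)
            )
            total += c * p
        loglik_cache[key] = total
        structures[key] = struct
        return total

    def acyclic_after(t: str, trial_edges: set[tuple[int, int]]) -> bool:
        labels = sorted(set(z))
        idx = {l: i for i, l in enumerate(labels)}
        pairs = [(idx[s], idx[d]) for (s, d) in trial_edges if s != d]
        return _is_acyclic(len(labels), pairs)

    accept_counts = {"agent": 0, "agent_total": 0, "edge": 0, "edge_total": 0}
    cur_ll = current_loglik()

    def sweep():
        nonlocal next_label, cur_ll
        # --- per-agent reassignment --------------------------------------
        for a in rng.permutation(n):
            a = int(a)
            la = z[a]
            members[la].remove(a)
            dying = len(members[la]) == 0
            labels = [l for l, m in members.items() if m]
            weights = [float(len(members[l])) for l in labels]
            labels.append(-1)  # new cluster sentinel
            weights.append(alpha)
            u = rng.random() * sum(weights)
            acc = 0.0
            choice = labels[-1]
            for lbl, wt in zip(labels, weights):
                acc += wt
                if u < acc:
                    choice = lbl
                    break
            if choice == la and not dying:
                members[la].append(a)
                accept_counts["agent"] += 1
                accept_counts["agent_total"] += 1
                continue

            # stash rollback info
            removed_edges = {
                t: {e for e in edges[t] if la in e} for t in types
            } if dying else None
            accept_counts["agent_total"] += 1

            if dying:
                for t in types:
                    edges[t] -= removed_edges[t]
            if choice == -1:
                nl = next_label
                next_label += 1
                drawn: dict[str, set[tuple[int, int]]] = {t: set() for t in types}
                other_labels = [l for l, m in members.items() if m]
                for t in directed:
                    for l in other_labels:
                        u = rng.random()
                        if u < p_edge:
                            drawn[t].add((nl, l) if rng.random() < 0.5 else (l, nl))
                if has_friend and rng.random() < p_edge:
                    drawn[FRIENDSHIP].add((nl, nl))
                z[a] = nl
                members[nl] = [a]
                for t in types:
                    edges[t] |= drawn[t]
                ok = all(acyclic_after(t, edges[t]) for t in directed)
            else:
                z[a] = choice
                members[choice].append(a)
                drawn = None
                ok = True  # moving between existing clusters keeps the cluster graph

            if ok:
                new_ll = current_loglik()
                ok = math.log(rng.random()) < new_ll - cur_ll if new_ll < cur_ll else True
            if ok:
                cur_ll = new_ll
                accept_counts["agent"] += 1
                if dying:
                    del members[la]
            else:
                # rollback
                if choice == -1:
                    for t in types:
                        edges[t] -= drawn[t]
                    del members[nl]
                else:
                    members[choice].remove(a)
                if dying:
                    for t in types:
                        edges[t] |= removed_edges[t]
                z[a] = la
                members[la].append(a)

        # --- edge resampling ---------------------------------------------
        labels = sorted(l for l, m in members.items() if m)
        for t in directed:
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    l1, l2 = labels[i], labels[j]
                    cur = (
                        (l1, l2) if (l1, l2) in edges[t]
                        else (l2, l1) if (l2, l1) in edges[t]
                        else None
                    )
                    u = rng.random()
                    if u < 1 - p_edge:
                        prop = None
                    elif u < 1 - p_edge / 2:
                        prop = (l1, l2)
                    else:
                        prop = (l2, l1)
                    if prop == cur:
                        accept_counts["edge"] += 1
                        accept_counts["edge_total"] += 1
                        continue
                    accept_counts["edge_total"] += 1
                    if cur is not None:
                        edges[t].discard(cur)
                    if prop is not None:
                        edges[t].add(prop)
                    ok = prop is None or acyclic_after(t, edges[t])
                    if ok:
                        new_ll = current_loglik()
                        ok = (
                            True
                            if new_ll >= cur_ll
                            else math.log(rng.random()) < new_ll - cur_ll
                        )
                    if ok:
                        cur_ll = new_ll
                        accept_counts["edge"] += 1
                    else:
                        if prop is not None:
                            edges[t].discard(prop)
                        if cur is not None:
                            edges[t].add(cur)
        if has_friend:
            for l in labels:
                cur_loop = (l, l) in edges[FRIENDSHIP]
                prop_loop = rng.random() < p_edge
                accept_counts["edge_total"] += 1
                if prop_loop == cur_loop:
                    accept_counts["edge"] += 1
                    continue
                if prop_loop:
                    edges[FRIENDSHIP].add((l, l))
                else:
                    edges[FRIENDSHIP].discard((l, l))
                new_ll = current_loglik()
                ok = True if new_ll >= cur_ll else math.log(rng.random()) < new_ll - cur_ll
                if ok:
                    cur_ll = new_ll
                    accept_counts["edge"] += 1
                else:
                    if prop_loop:
                        edges[FRIENDSHIP].discard((l, l))
                    else:
                        edges[FRIENDSHIP].add((l, l))

    counts: Counter[tuple] = Counter()
    total_iters = cfg.burn_in + cfg.n_samples * cfg.thin
    kept = 0
    for it in range(total_iters):
        sweep()
        if not math.isfinite(cur_ll):
            raise InferenceError("non-finite log posterior encountered during MH")
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            key = state_key()
            if key not in structures:
                structures[key] = build_structure()
            counts[key] += 1
            kept += 1

    support_keys = sorted(counts, key=lambda k: (-counts[k], structures[k].sort_key))
    support = [structures[k] for k in support_keys]
    probs = np.array([counts[k] for k in support_keys], dtype=float) / kept
    diagnostics = {
        "agent_move_acceptance": accept_counts["agent"] / max(accept_counts["agent_total"], 1),
        "edge_move_acceptance": accept_counts["edge"] / max(accept_counts["edge_total"], 1),
        "n_sweeps": total_iters,
        "n_kept": kept,
        "effective_support": len(support),
        "n_likelihood_evals": len(loglik_cache),
    }
    return StructurePosterior(
        support=support,
        probabilities=probs,
        provenance="mh",
        diagnostics=diagnostics,
    )
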