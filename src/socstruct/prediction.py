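"""Downstream queries over the structure posterior.

Next-interaction prediction marginalizes the recipient stage over the
posterior, P(d | D) = sum_S P(d | S) P(S | D), conditioning on the recipient
lying in the stated candidate set (an absent agent is simply unavailable and
does not alter the inferred structure).  Influence queries read posterior
relation marginals, P(i has relation r to j | D) = sum_S 1[r holds in S] P(S | D).
The frequency-tracking baselines use raw interaction counts instead of any
structure representation: undirected pair counts for next-interaction
prediction, directed initiator->decider counts for influence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import StructurePosterior
from .sociology import InteractionSequence, SociologyParams, stage_distributions
from .structures import RELATION_FOR_LABEL, RELATION_QUERIES, relation_holds

logger = logging.getLogger("socstruct.prediction")

#: Experiment-3 influence questions and the relation each one probes
QUESTION_RELATION = {
    "extra_shift": "manager_of",
    "movie": "friend_of",
    "optional_class": "mentor_of",
}


@dataclass(frozen=True)
class PredictionQuery:
    """Who will ``initiator`` direct the next interaction of this type at?"""

    initiator: str
    interaction_type: str
    candidates: tuple[str, ...]
    absent: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("candidate set must be nonempty")
        if self.initiator in self.absent:
            raise ValueError("the initiator cannot be absent")
        if self.initiator in self.candidates:
            raise ValueError("the initiator cannot be a candidate recipient")
        if set(self.candidates) & set(self.absent):
            raise ValueError("candidates and absent agents must be disjoint")


@dataclass(frozen=True)
class InfluenceQuery:
    """Which agent could convince ``decider``?  The question fixes the relation."""

    decider: str
    question: str

    def __post_init__(self):
        if self.question not in QUESTION_RELATION:
            raise ValueError(
                f"unknown question {self.question!r}; expected one of {sorted(QUESTION_RELATION)}"
            )

    @property
    def relation(self) -> str:
        return QUESTION_RELATION[self.question]


def predict_next_interaction(
    posterior: StructurePosterior,
    query: PredictionQuery,
    params: SociologyParams | None = None,
    relation: str | None = None,
    per_structure_renormalize: bool = False,
) -> dict[str, float]:
    """Posterior-predictive recipient distribution over the candidates.

    ``relation`` selects which sociology's recipient stage generates the
    prediction (default: the one matching the query's interaction type, as
    when the same module did the inferring).  The default conditions the
    marginalized mixture on the candidate set; ``per_structure_renormalize``
    instead renormalizes within each structure before mixing.
    """
    params = params or SociologyParams()
    rtype = relation or RELATION_FOR_LABEL[query.interaction_type]
    weights = dict.fromkeys(query.candidates, 0.0)
    for structure, p in posterior.items():
        tab = stage_distributions(structure, rtype, params)
        row = tab.recipient[query.initiator]
        if per_structure_renormalize:
            z = sum(row[c] for c in query.candidates)
            for c in query.candidates:
                weights[c] += p * row[c] / z
        else:
            for c in query.candidates:
                weights[c] += p * row[c]
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no candidate receives positive predictive mass")
    return {c: w / total for c, w in weights.items()}


def relation_probability(
    posterior: StructurePosterior,
    relation: str,
    i: str,
    j: str,
    transitive: bool = False,
) -> float:
    """P(i stands in ``relation`` to j | D): the posterior-weighted indicator."""
    if relation not in RELATION_QUERIES:
        raise ValueError(f"unknown relation {relation!r}")
    if i == j:
        raise ValueError("relation queries require two distinct agents")
    return posterior.expectation(
        lambda s: 1.0 if relation_holds(s, relation, i, j, transitive=transitive) else 0.0
    )


def influence_scores(
    posterior: StructurePosterior,
    query: InfluenceQuery,
    transitive: bool = False,
) -> dict[str, float]:
    """Each other agent's influence over the decider: the mapped relation's marginal."""
    agents = posterior.support[0].agents
    if query.decider not in agents:
        raise KeyError(f"unknown decider {query.decider!r}")
    return {
        i: relation_probability(posterior, query.relation, i, query.decider, transitive)
        for i in agents
        if i != query.decider
    }


def frequency_predict(
    D: InteractionSequence,
    query: PredictionQuery,
    mode: str = "expected",
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Frequency-tracking next-interaction baseline.

    Candidate weight = number of interactions (either direction, any type)
    between the query's initiator and the candidate.  Unobserved pairs take
    0.5 (``mode='expected'``, the mean of the uniform prior) or a seeded
    Uniform(0, 1) draw (``mode='sampled'``); weights are renormalized over
    the candidates.
    """
    if mode not in ("expected", "sampled"):
        raise ValueError("mode must be 'expected' or 'sampled'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = {}
    for c in query.candidates:
        count = sum(
            1
            for d in D.interactions
            if {d.initiator, d.recipient} == {query.initiator, c}
        )
        if count == 0:
            weights[c] = 0.5 if mode == "expected" else float(rng.random())
        else:
            weights[c] = float(count)
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


def frequency_influence(D: InteractionSequence, decider: str) -> dict[str, float]:
    """Directed frequency baseline: how often each agent initiated toward the decider."""
    if decider not in D.agents:
        raise KeyError(f"unknown decider {decider!r}")
    return {
        i: float(
            sum(1 for d in D.interactions if d.initiator == i and d.recipient == decider)
        )
        for i in D.agents
        if i != decider
    }
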