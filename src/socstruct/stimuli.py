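"""Stimulus-sequence generation, informativeness filters and trial selection.

Random sequences are drawn uniformly over the single-step outcome space
(ordered distinct agent pair x interaction type x response; 120 outcomes for
5 agents, 3 types, 2 responses).  Candidate stimuli are screened by three
informativeness rules — no interaction tuple repeated more than twice, at
most one uninvolved agent, and between one and two rejections — and trials
are then selected either to hit target posterior "probability profiles"
(structure-inference studies) or to maximize the sum-squared divergence
between a main and an alternate model's predictions (prediction studies).
"""
from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .sociology import Interaction, InteractionSequence
from .structures import INTERACTION_LABELS, RESPONSES, SocialStructure

logger = logging.getLogger("socstruct.stimuli")

FILTER_RULES = ("repeat_rule", "isolation_rule", "rejection_rule")
PROFILE_LABELS = ("one_high", "high_and_moderate", "two_high", "three_moderate")


def outcome_space(
    agents: Sequence[str],
    allowed_types: Sequence[str] = INTERACTION_LABELS,
) -> list[tuple[str, str, str, str]]:
    """All (initiator, recipient, type, response) single-step outcomes."""
    return [
        (i, j, t, r)
        for i, j in itertools.permutations(agents, 2)
        for t in allowed_types
        for r in RESPONSES
    ]


def generate_random_sequence(
    agents: Sequence[str],
    length: int,
    allowed_types: Sequence[str] = INTERACTION_LABELS,
    seed: int | np.random.Generator | None = None,
) -> InteractionSequence:
    """Each step uniform over the outcome space; reproducible given a seed."""
    if length < 1:
        raise ValueError("length must be at least 1")
    if len(agents) < 2:
        raise ValueError("need at least 2 agents")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = outcome_space(agents, allowed_types)
    picks = rng.integers(0, len(space), size=length)
    steps = tuple(
        Interaction(type=space[k][2], initiator=space[k][0], recipient=space[k][1], response=space[k][3])
        for k in picks
    )
    return InteractionSequence(interactions=steps, agents=tuple(agents))


@dataclass(frozen=True)
class StimulusFilterReport:
    passed: bool
    violations: tuple[str, ...]


def passes_filters(
    D: InteractionSequence,
    multi_type_mode: bool | None = None,
) -> StimulusFilterReport:
    """Apply the three informativeness rules.

    ``multi_type_mode`` controls whether the repeat rule's "same interaction"
    tuple includes the interaction type (defaults to True when the sequence
    mixes types; for single-type sequences the two readings coincide).
    """
    if multi_type_mode is None:
        multi_type_mode = len(set(d.type for d in D.interactions)) > 1
    violations = []

    if multi_type_mode:
        tuples = Counter((d.initiator, d.recipient, d.response, d.type) for d in D.interactions)
    else:
        tuples = Counter((d.initiator, d.recipient, d.response) for d in D.interactions)
    if any(c > 2 for c in tuples.values()):
        violations.append("repeat_rule")

    involved = set()
    for d in D.interactions:
        involved.add(d.initiator)
        involved.add(d.recipient)
    if len(set(D.agents) - involved) > 1:
        violations.append("isolation_rule")

    n_rejected = sum(1 for d in D.interactions if d.response == "reject")
    if not 1 <= n_rejected <= 2:
        violations.append("rejection_rule")

    return StimulusFilterReport(passed=not violations, violations=tuple(violations))


def generate_filtered_pool(
    agents: Sequence[str],
    length: int,
    allowed_types: Sequence[str] = INTERACTION_LABELS,
    pool_size: int = 10_000,
    seed: int | np.random.Generator | None = None,
    require_all_types: bool = False,
) -> list[InteractionSequence]:
    """Draw ``pool_size`` random sequences and keep those passing the filters.

    ``require_all_types`` adds the mixed-type studies' extra constraint that
    every allowed interaction type appears at least once.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = []
    for _ in range(pool_size):
        seq = generate_random_sequence(agents, length, allowed_types, rng)
        if not passes_filters(seq).passed:
            continue
        if require_all_types and set(d.type for d in seq.interactions) != set(allowed_types):
            continue
        pool.append(seq)
    logger.info("filtered pool: kept %d of %d sequences", len(pool), pool_size)
    return pool


# ---------------------------------------------------------------------------
# Trial selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityProfile:
    """Threshold bands for classifying a trial's top-4 posterior probabilities.

    high: p >= high_min; moderate: moderate_min < p < high_min;
    improbable: p < improbable_max; in between is borderline (unclassified).
    """

    high_min: float = 0.6
    moderate_min: float = 0.15
    improbable_max: float = 0.10

    def __post_init__(self):
        if not self.high_min > self.moderate_min > self.improbable_max:
            raise ValueError("thresholds must satisfy high_min > moderate_min > improbable_max")


def classify_profile(
    top_probs: Sequence[float],
    thresholds: ProbabilityProfile | None = None,
) -> str | None:
    """Map a descending top-4 probability vector to a profile label (or None).

    one_high: 1 high + 3 improbable; high_and_moderate: 1 high + 1 moderate
    + 2 improbable; two_high: 2 moderate-or-better + 2 improbable (no single
    dominant structure); three_moderate: 3 moderate + 1 non-probable.  The
    patterns are mutually exclusive, so each vector maps to at most one label.
    """
    th = thresholds or ProbabilityProfile()
    p = sorted((float(x) for x in top_probs), reverse=True)
    n_high = sum(x >= th.high_min for x in p)
    n_mod = sum(th.moderate_min < x < th.high_min for x in p)
    n_imp = sum(x < th.improbable_max for x in p)
    n_nonprob = sum(x <= th.moderate_min for x in p)
    if n_high == 1 and n_imp == 3:
        return "one_high"
    if n_high == 1 and n_mod == 1 and n_imp == 2:
        return "high_and_moderate"
    if n_high == 0 and n_mod == 2 and n_imp == 2:
        return "two_high"
    if n_high == 0 and n_mod == 3 and n_nonprob == 1:
        return "three_moderate"
    return None


@dataclass
class SelectedTrial:
    sequence: InteractionSequence
    top_structures: list[tuple[SocialStructure, float]]
    profile: str
    pool_index: int


def select_trials_by_profile(
    pool: Sequence[InteractionSequence],
    infer_top4: Callable[[InteractionSequence], list[tuple[SocialStructure, float]]],
    profiles: Sequence[str] = PROFILE_LABELS,
    per_profile: int = 2,
    thresholds: ProbabilityProfile | None = None,
) -> dict[str, list[SelectedTrial]]:
    """First-found selection of ``per_profile`` sequences matching each profile.

    ``infer_top4`` is the model pipeline (inference followed by top-4
    extraction).  Deterministic given pool order and the pipeline's seeding;
    profiles that cannot be filled are reported with a warning.
    """
    selected: dict[str, list[SelectedTrial]] = {label: [] for label in profiles}
    if not pool:
        logger.warning("empty stimulus pool; nothing selected")
        return selected
    for idx, seq in enumerate(pool):
        if all(len(v) >= per_profile for v in selected.values()):
            break
        top4 = infer_top4(seq)
        label = classify_profile([p for _, p in top4], thresholds)
        if label in selected and len(selected[label]) < per_profile:
            selected[label].append(
                SelectedTrial(sequence=seq, top_structures=top4, profile=label, pool_index=idx)
            )
    for label, trials in selected.items():
        if len(trials) < per_profile:
            logger.warning(
                "profile %s: only %d of %d trials matched", label, len(trials), per_profile
            )
    return selected


def select_trials_by_divergence(
    pool: Sequence[InteractionSequence],
    main_predictions: Sequence[Sequence[float]],
    alt_predictions: Sequence[Sequence[float]],
    k: int,
) -> list[int]:
    """Indices of the k pool sequences where the models disagree the most.

    Divergence is the sum of squared differences between the aligned
    prediction vectors; descending order with pool-index tie-breaks.
    """
    if len(main_predictions) != len(pool) or len(alt_predictions) != len(pool):
        raise ValueError("predictions must align one-to-one with the pool")
    scores = []
    for idx, (m, a) in enumerate(zip(main_predictions, alt_predictions)):
        m = np.asarray(m, dtype=float)
        a = np.asarray(a, dtype=float)
        if m.shape != a.shape:
            raise ValueError(f"prediction vectors for pool item {idx} have mismatched lengths")
        scores.append((float(np.sum((m - a) ** 2)), idx))
    if k > len(pool):
        logger.warning("requested %d trials from a pool of %d; returning all", k, len(pool))
        k = len(pool)
    ranked = sorted(scores, key=lambda si: (-si[0], si[1]))
    return [idx for _, idx in ranked[:k]]
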