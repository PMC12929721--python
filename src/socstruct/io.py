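"""Readers/writers, run configuration and the seeded fixture generator.

Canonical on-disk formats are plain text: structures as JSON
(``{"agents": [...], "clusters": [[...], ...], "edges": [{"type", "from",
"to"}]}``), interaction sequences as JSON lines (one event per line with
``trial_id``/``step`` fields; CSV is an accepted fallback), posteriors as
JSON ranked lists, and response tables as CSV.  All randomness in the
fixture generator flows from a single seed so bundles are byte-stable.
"""
from __future__ import annotations

import csv
import io as _io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .inference import MCMCConfig, StructurePosterior, mh_posterior, top_k_structures
from .prediction import PredictionQuery, frequency_predict, predict_next_interaction
from .prior import PriorConfig
from .sociology import (
    AuthorityParams,
    FriendshipParams,
    Interaction,
    InteractionSequence,
    MentorshipParams,
    SociologyParams,
)
from .stimuli import generate_filtered_pool
from .structures import (
    INTERACTION_LABELS,
    RELATION_FOR_LABEL,
    RESPONSES,
    SocialStructure,
    require_valid,
)

logger = logging.getLogger("socstruct.io")

DEFAULT_AGENTS = ("Pink", "Blue", "Yellow", "Green", "Grey")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def structure_to_dict(structure: SocialStructure) -> dict:
    return {
        "agents": list(structure.agents),
        "clusters": [list(c) for c in structure.clusters],
        "edges": [
            {"type": t, "from": s, "to": d} for (t, s, d) in sorted(structure.edges)
        ],
    }


def structure_from_dict(data: Mapping) -> SocialStructure:
    try:
        structure = SocialStructure(
            agents=tuple(data["agents"]),
            clusters=tuple(tuple(c) for c in data["clusters"]),
            edges=frozenset(
                (e["type"], int(e["from"]), int(e["to"])) for e in data.get("edges", [])
            ),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed structure JSON: {exc}") from exc
    require_valid(structure)
    return structure


def write_structure(path: str | Path, structure: SocialStructure) -> None:
    Path(path).write_text(json.dumps(structure_to_dict(structure), indent=2) + "\n")


def read_structure(path: str | Path) -> SocialStructure:
    return structure_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Interaction sequences
# ---------------------------------------------------------------------------

def _validate_record(rec: Mapping, where: str) -> None:
    t = rec.get("type")
    if t not in RELATION_FOR_LABEL:
        raise ParseError(f"{where}: unknown interaction type {t!r}")
    if rec.get("response") not in RESPONSES:
        raise ParseError(f"{where}: unknown response {rec.get('response')!r}")
    if rec.get("initiator") == rec.get("recipient"):
        raise ParseError(f"{where}: initiator equals recipient")


def write_interactions(
    path: str | Path,
    sequences: Mapping[str, InteractionSequence],
    fmt: str = "jsonl",
) -> None:
    rows = []
    for trial_id, seq in sequences.items():
        for step, d in enumerate(seq.interactions):
            rows.append(
                {
                    "trial_id": trial_id,
                    "step": step,
                    "type": d.type,
                    "initiator": d.initiator,
                    "recipient": d.recipient,
                    "response": d.response,
                }
            )
    path = Path(path)
    if fmt == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["trial_id", "step", "type", "initiator", "recipient", "response"]
            )
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError("fmt must be 'jsonl' or 'csv'")


def read_interactions(
    path: str | Path,
    agents: Sequence[str] | None = None,
) -> dict[str, InteractionSequence]:
    """Load trial-grouped sequences from JSON lines or CSV (sniffed by suffix).

    Schema violations are reported with their line number.  The agent set
    defaults to the agents observed across the whole file, in order of first
    appearance, unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[int, dict]] = []
    text = path.read_text()
    if not text.strip():
        logger.warning("%s is empty; returning no sequences", path)
        return {}
    if path.suffix == ".csv":
        reader = csv.DictReader(_io.StringIO(text))
        for lineno, rec in enumerate(reader, start=2):
            records.append((lineno, rec))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                records.append((lineno, json.loads(line)))
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({exc})") from exc

    for lineno, rec in records:
        _validate_record(rec, f"{path}:{lineno}")

    if agents is None:
        seen: dict[str, None] = {}
        for _, rec in records:
            seen.setdefault(rec["initiator"])
            seen.setdefault(rec["recipient"])
        agents = tuple(seen)
    else:
        agents = tuple(agents)
        known = set(agents)
        for lineno, rec in records:
            for role in ("initiator", "recipient"):
                if rec[role] not in known:
                    raise ParseError(f"{path}:{lineno}: unknown agent {rec[role]!r}")

    grouped: dict[str, list[tuple[int, dict]]] = {}
    for lineno, rec in records:
        grouped.setdefault(str(rec.get("trial_id", "trial0")), []).append((lineno, rec))
    out = {}
    for trial_id, recs in grouped.items():
        recs.sort(key=lambda lr: int(lr[1].get("step", lr[0])))
        steps = tuple(
            Interaction(
                type=rec["type"],
                initiator=rec["initiator"],
                recipient=rec["recipient"],
                response=rec["response"],
            )
            for _, rec in recs
        )
        out[trial_id] = InteractionSequence(interactions=steps, agents=agents)
    return out


# ---------------------------------------------------------------------------
# Posteriors and predictions
# ---------------------------------------------------------------------------

def posterior_to_dict(posterior: StructurePosterior, top: int | None = None) -> dict:
    items = top_k_structures(posterior, top) if top else list(posterior.items())
    return {
        "structures": [
            {"structure": structure_to_dict(s), "prob": float(p)} for s, p in items
        ],
        "provenance": posterior.provenance,
        "diagnostics": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in posterior.diagnostics.items()
        },
    }


def write_posterior(path: str | Path, posterior: StructurePosterior, top: int | None = None) -> None:
    Path(path).write_text(json.dumps(posterior_to_dict(posterior, top), indent=2) + "\n")


def write_predictions_csv(path: str | Path, rows: Iterable[Mapping]) -> None:
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    params: SociologyParams = field(default_factory=SociologyParams)
    seed: int = 0
    log_level: str = "INFO"


def _params_from_mapping(data: Mapping) -> SociologyParams:
    def section(name, cls):
        raw = dict(data.get(name, {}))
        # accept flat dotted keys too ("authority.beta_down")
        for key, val in data.items():
            if isinstance(key, str) and key.startswith(name + "."):
                raw[key.split(".", 1)[1]] = val
        return cls(**raw)

    return SociologyParams(
        authority=section("authority", AuthorityParams),
        friendship=section("friendship", FriendshipParams),
        mentorship=section("mentorship", MentorshipParams),
    )


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    prior = PriorConfig(**data.get("prior", {}))
    mcmc = MCMCConfig(**data.get("mcmc", {}))
    params = _params_from_mapping(data.get("params", {}))
    return RunConfig(
        prior=prior,
        mcmc=mcmc,
        params=params,
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
    )


def save_config(path: str | Path, config: RunConfig) -> None:
    data = {
        "prior": asdict(config.prior),
        "mcmc": asdict(config.mcmc),
        "params": asdict(config.params),
        "seed": config.seed,
        "log_level": config.log_level,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """A deterministic bundle emulating one experiment's data shapes."""

    experiment: str
    agents: tuple[str, ...]
    sequences: dict[str, InteractionSequence]
    candidate_structures: dict[str, list[tuple[SocialStructure, float]]]
    queries: dict[str, PredictionQuery]
    predictions: pd.DataFrame
    responses: pd.DataFrame


def make_fixtures(
    experiment: str,
    seed: int = 0,
    n_trials: int = 2,
    n_participants: int = 12,
    mcmc_samples: int = 3000,
    burn_in: int = 300,
    pool_size: int = 400,
) -> FixtureBundle:
    """Build a seeded fixture bundle shaped like one of the three studies.

    exp1: length-8 single-type sequences with 4 candidate structures per
    trial and Likert-7 responses; exp2: length-8 sequences with an
    absent-agent prediction query and slider responses; exp3: length-6
    mixed-type sequences with at least one interaction of each type.
    Reduced sampling keeps fixtures fast; everything derives from ``seed``.
    """
    from .evaluation import RespondentNoiseModel, simulate_respondents

    if experiment not in ("exp1", "exp2", "exp3"):
        raise ValueError("experiment must be one of exp1, exp2, exp3")
    rng = np.random.default_rng(seed)
    agents = DEFAULT_AGENTS
    params = SociologyParams()
    mcfg = lambda s: MCMCConfig(n_samples=mcmc_samples, burn_in=burn_in, seed=s)

    if experiment == "exp3":
        pool = generate_filtered_pool(
            agents, length=6, allowed_types=INTERACTION_LABELS,
            pool_size=pool_size, seed=rng, require_all_types=True,
        )
        types = ("authority", "friendship", "mentorship")
        label = "order"
    else:
        pool = generate_filtered_pool(
            agents, length=8, allowed_types=("order",), pool_size=pool_size, seed=rng
        )
        types = ("authority",)
        label = "order"

    sequences = {f"trial{i}": pool[i] for i in range(min(n_trials, len(pool)))}

    candidates: dict[str, list[tuple[SocialStructure, float]]] = {}
    queries: dict[str, PredictionQuery] = {}
    pred_rows = []
    for i, (trial_id, seq) in enumerate(sequences.items()):
        posterior = mh_posterior(seq, types, params, mcmc_config=mcfg(seed * 1000 + i))
        if experiment == "exp1":
            top4 = top_k_structures(posterior, 4)
            candidates[trial_id] = top4
            for rank, (_, p) in enumerate(top4):
                pred_rows.append(
                    {"trial_id": trial_id, "item_id": f"s{rank}", "prediction": p}
                )
        elif experiment == "exp2":
            initiator, absent = agents[0], agents[2]
            cands = tuple(a for a in agents if a not in (initiator, absent))
            query = PredictionQuery(
                initiator=initiator, interaction_type=label,
                candidates=cands, absent=(absent,),
            )
            queries[trial_id] = query
            pred = predict_next_interaction(posterior, query, params)
            for cand, p in pred.items():
                pred_rows.append({"trial_id": trial_id, "item_id": cand, "prediction": p})
        else:
            from .prediction import InfluenceQuery, influence_scores

            query = InfluenceQuery(decider=agents[0], question="extra_shift")
            scores = influence_scores(posterior, query)
            for agent, p in scores.items():
                pred_rows.append({"trial_id": trial_id, "item_id": agent, "prediction": p})

    predictions = pd.DataFrame(pred_rows)
    noise = RespondentNoiseModel(
        discretization="likert7" if experiment in ("exp1", "exp3") else "slider",
        noise_sd=0.3,
        seed=seed + 17,
    )
    responses = simulate_respondents(predictions, noise, n_participants)
    return FixtureBundle(
        experiment=experiment,
        agents=agents,
        sequences=sequences,
        candidate_structures=candidates,
        queries=queries,
        predictions=predictions,
        responses=responses,
    )
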