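"""Judgment-analysis layer: preprocessing, correlations, bootstrap contrasts.

Mirrors the behavioral analyses the model predictions feed into: responses
are z-scored within participant (Likert studies) or normalized to per-trial
probability distributions (slider studies), averaged across participants,
and compared to model predictions by Pearson correlation.  Model contrasts
use bootstrapped (participant-resampled) 95% confidence intervals on the
difference in correlation, significant when the interval lies entirely above
zero.  A synthetic-respondent generator emulates the shape of the deposited
judgment tables (n participants x trials x items, Likert-7 or 0-100 slider)
so the whole layer is testable without any external download.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("socstruct.evaluation")

RESPONSE_COLUMNS = ["participant_id", "trial_id", "item_id", "value", "scale"]


class DegenerateGroupError(ValueError):
    """A z-score group with fewer than two values or zero variance."""


def zscore(values: Sequence[float], ddof: int = 1) -> np.ndarray:
    """Z-score a single group (sample SD by default; ddof=0 for population SD)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateGroupError("z-scoring needs at least 2 values per group")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise DegenerateGroupError("z-scoring a zero-variance group")
    return (x - x.mean()) / sd


def zscore_within(
    table: pd.DataFrame,
    value_col: str = "value",
    group_cols: Sequence[str] | str = "participant_id",
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-score ``value_col`` within each group; returns a copy with the column replaced.

    Raises :class:`DegenerateGroupError` naming the offending group rather
    than silently producing NaNs.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    out = table.copy()
    for key, idx in out.groupby(list(group_cols)).groups.items():
        vals = out.loc[idx, value_col].to_numpy(dtype=float)
        if vals.size < 2 or vals.std(ddof=ddof) == 0:
            raise DegenerateGroupError(
                f"group {key!r} has {vals.size} value(s) with SD "
                f"{vals.std(ddof=ddof) if vals.size > 1 else float('nan'):.3g}"
            )
        out.loc[idx, value_col] = zscore(vals, ddof=ddof)
    return out


def normalize_to_distribution(values: Sequence[float]) -> np.ndarray:
    """Scale nonnegative slider values to a probability vector (sum 1)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("slider values must be nonnegative")
    total = x.sum()
    if total == 0:
        logger.warning("all-zero trial responses; falling back to uniform")
        return np.full(x.shape, 1.0 / x.size)
    return x / total


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Bootstrap difference-in-correlation
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    diff: float
    ci_low: float
    ci_high: float
    significant: bool
    replicates: np.ndarray


def _item_matrix(responses: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Participants x items response matrix (NaN where a participant skipped)."""
    wide = responses.pivot_table(
        index="participant_id", columns=["trial_id", "item_id"], values="value"
    )
    return wide.to_numpy(dtype=float), list(wide.columns)


def bootstrap_diff_correlation(
    responses: pd.DataFrame,
    predictions_main: Mapping[tuple, float] | pd.Series,
    predictions_alt: Mapping[tuple, float] | pd.Series,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
    ci: float = 0.95,
) -> BootstrapResult:
    """Percentile CI for r(main, judgments) - r(alt, judgments).

    Participants are the resampling unit (matching the per-participant
    preprocessing); each replicate re-averages the resampled participants'
    responses per item and recomputes both correlations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat, items = _item_matrix(responses)
    n_part = mat.shape[0]
    if n_part < 2:
        raise ValueError("bootstrapping needs at least 2 participants")
    pm = np.array([predictions_main[item] for item in items], dtype=float)
    pa = np.array([predictions_alt[item] for item in items], dtype=float)

    def corr_rows(rows: np.ndarray, preds: np.ndarray) -> np.ndarray:
        # row-wise Pearson of each replicate's item means against preds
        x = rows - rows.mean(axis=1, keepdims=True)
        y = preds - preds.mean()
        num = x @ y
        den = np.sqrt((x ** 2).sum(axis=1) * (y ** 2).sum())
        return num / den

    idx = rng.integers(0, n_part, size=(n_boot, n_part))
    with np.errstate(invalid="ignore"):
        means = np.nanmean(mat[idx], axis=1)
        diffs = corr_rows(means, pm) - corr_rows(means, pa)
        observed = float(
            corr_rows(np.nanmean(mat, axis=0)[None, :], pm)[0]
            - corr_rows(np.nanmean(mat, axis=0)[None, :], pa)[0]
        )
    tail = (1.0 - ci) / 2.0
    lo, hi = np.nanquantile(diffs, [tail, 1.0 - tail])
    return BootstrapResult(
        diff=observed,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0),
        replicates=diffs,
    )


# ---------------------------------------------------------------------------
# Synthetic respondents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RespondentNoiseModel:
    """Synthetic stand-in for human raters, emulating the judgment tables' shape.

    The latent response is an affine map of the model probability plus
    Gaussian noise, discretized to the study's scale: ``slider`` maps p to
    100p clipped to [0, 100]; ``likert7`` min-max scales predictions within
    each trial onto 1..7 and rounds.
    """

    discretization: str = "slider"  # or "likert7"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.discretization not in ("slider", "likert7"):
            raise ValueError("discretization must be 'slider' or 'likert7'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_respondents(
    predictions: pd.DataFrame,
    noise: RespondentNoiseModel,
    n_participants: int,
) -> pd.DataFrame:
    """Draw a ResponseTable from model predictions under the noise model.

    ``predictions`` needs columns ``trial_id``, ``item_id``, ``prediction``.
    Noise is applied on the latent response scale, independently per
    participant and item; the result has one row per participant x trial x
    item with columns {participant_id, trial_id, item_id, value, scale}.
    """
    required = {"trial_id", "item_id", "prediction"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions must have columns {sorted(required)}")
    rng = np.random.default_rng(noise.seed)

    preds = predictions.copy()
    if noise.discretization == "slider":
        preds["latent"] = 100.0 * preds["prediction"].astype(float)
    else:
        def scale_trial(g: pd.Series) -> pd.Series:
            lo, hi = g.min(), g.max()
            span = hi - lo
            scaled = (g - lo) / span if span > 0 else pd.Series(0.5, index=g.index)
            return 1.0 + 6.0 * scaled

        preds["latent"] = preds.groupby("trial_id")["prediction"].transform(scale_trial)

    rows = []
    for p in range(n_participants):
        latent = preds["latent"].to_numpy() + rng.normal(0.0, noise.noise_sd, len(preds))
        if noise.discretization == "slider":
            value = np.clip(latent, 0.0, 100.0)
        else:
            value = np.clip(np.rint(latent), 1, 7)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": f"p{p:03d}",
                    "trial_id": preds["trial_id"].to_numpy(),
                    "item_id": preds["item_id"].to_numpy(),
                    "value": value,
                    "scale": noise.discretization,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# End-to-end synthetic prediction study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Correlations and contrasts from one synthetic next-interaction study."""

    r_by_model: dict[str, float]
    main_model: str
    contrasts: dict[str, BootstrapResult]
    predictions: pd.DataFrame
    responses: pd.DataFrame
    n_trials: int
    n_participants: int


def synthetic_prediction_study(
    seed: int = 0,
    main_relation: str = "authority",
    n_trials: int = 4,
    n_candidate_pool: int = 12,
    sequence_length: int = 8,
    n_participants: int = 20,
    noise_sd: float = 2.0,
    mcmc_samples: int = 8000,
    burn_in: int = 800,
    n_boot: int = 2000,
) -> StudyResult:
    """Run the full pipeline on synthetic data: stimuli -> posterior ->
    predictions -> simulated sliders -> correlation analysis.

    Emulates the next-interaction study shape: filtered single-type stimulus
    sequences over five agents, trials selected where the structured model
    and the frequency baseline diverge most, one absent-agent recipient query
    per trial, slider respondents generated from the main model's
    predictions under Gaussian noise (sd on the 0-100 scale), and Pearson
    correlations of every model variant against the averaged, per-trial
    normalized responses, with participant-bootstrap contrasts against the
    main model.
    """
    from .inference import MCMCConfig, mh_posterior
    from .prediction import PredictionQuery, frequency_predict, predict_next_interaction
    from .sociology import SociologyParams
    from .stimuli import generate_filtered_pool, select_trials_by_divergence
    from .structures import INTERACTION_LABEL, RELATION_TYPES

    agents = ("Pink", "Blue", "Yellow", "Green", "Grey")
    label = INTERACTION_LABEL[main_relation]
    params = SociologyParams()
    rng = np.random.default_rng(seed)
    pool = generate_filtered_pool(
        agents, sequence_length, (label,), pool_size=60 * n_candidate_pool, seed=rng
    )[:n_candidate_pool]

    def query_for(seq) -> PredictionQuery:
        first = seq.interactions[0]
        cands = tuple(a for a in agents if a not in (first.initiator, first.recipient))
        return PredictionQuery(
            initiator=first.initiator,
            interaction_type=label,
            candidates=cands,
            absent=(first.recipient,),
        )

    def posterior_for(seq, relation, chain_seed):
        return mh_posterior(
            seq,
            (relation,),
            params,
            mcmc_config=MCMCConfig(n_samples=mcmc_samples, burn_in=burn_in, seed=chain_seed),
            relation_map={label: relation},
        )

    # trial selection: where the main model and the frequency baseline diverge
    main_preds, freq_preds = [], []
    for i, seq in enumerate(pool):
        q = query_for(seq)
        post = posterior_for(seq, main_relation, seed * 997 + i)
        mp = predict_next_interaction(post, q, params, relation=main_relation)
        fp = frequency_predict(seq, q, mode="expected")
        main_preds.append([mp[c] for c in q.candidates])
        freq_preds.append([fp[c] for c in q.candidates])
    chosen = select_trials_by_divergence(pool, main_preds, freq_preds, n_trials)

    rows = []
    for t, idx in enumerate(chosen):
        seq = pool[idx]
        q = query_for(seq)
        for m_idx, model in enumerate(RELATION_TYPES):
            if model == main_relation:
                pred = dict(zip(q.candidates, main_preds[idx]))
            else:
                post = posterior_for(seq, model, seed * 1009 + 31 * idx + m_idx)
                pred = predict_next_interaction(post, q, params, relation=model)
            for c, p in pred.items():
                rows.append({"model": model, "trial_id": f"t{t}", "item_id": c, "prediction": p})
        for c, p in frequency_predict(seq, q, mode="expected").items():
            rows.append({"model": "frequency", "trial_id": f"t{t}", "item_id": c, "prediction": p})
    predictions = pd.DataFrame(rows)

    main_table = predictions[predictions["model"] == main_relation].drop(columns="model")
    noise = RespondentNoiseModel(discretization="slider", noise_sd=noise_sd, seed=seed + 71)
    responses = simulate_respondents(main_table, noise, n_participants)
    averaged = average_responses(responses, normalize_trials=True)
    averaged = averaged.set_index(["trial_id", "item_id"])

    keys = list(averaged.index)
    r_by_model, pred_maps = {}, {}
    for model in list(RELATION_TYPES) + ["frequency"]:
        sub = predictions[predictions["model"] == model]
        pm = {(t, i): v for t, i, v in zip(sub["trial_id"], sub["item_id"], sub["prediction"])}
        pred_maps[model] = pm
        r_by_model[model] = pearson(
            [pm[k] for k in keys], averaged["mean_response"].to_numpy()
        )
    contrasts = {
        model: bootstrap_diff_correlation(
            responses, pred_maps[main_relation], pred_maps[model],
            n_boot=n_boot, seed=seed + 113,
        )
        for model in pred_maps
        if model != main_relation
    }
    return StudyResult(
        r_by_model=r_by_model,
        main_model=main_relation,
        contrasts=contrasts,
        predictions=predictions,
        responses=responses,
        n_trials=len(chosen),
        n_participants=n_participants,
    )


def average_responses(
    responses: pd.DataFrame,
    normalize_trials: bool = False,
) -> pd.DataFrame:
    """Average responses across participants per (trial, item).

    With ``normalize_trials`` each participant's trial responses are first
    normalized to a probability distribution over items (the slider-study
    preprocessing).
    """
    table = responses.copy()
    if normalize_trials:
        table["value"] = table.groupby(["participant_id", "trial_id"])["value"].transform(
            lambda g: normalize_to_distribution(g.to_numpy())
        )
    return (
        table.groupby(["trial_id", "item_id"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean_response"})
    )
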