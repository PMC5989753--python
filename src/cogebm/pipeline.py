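"""End-to-end orchestration: preprocessing -> mixtures -> ordering -> staging.

The full fit mirrors the study analysis: impute non-engagement scores,
residualize on ID level using YA-only regressions, fit a semisupervised KDE
mixture per biomarker (YA/OA initialized), build the participant-by-
biomarker probability matrix, maximize the sequence likelihood by greedy
ascent plus MCMC, and stage every participant along the winning sequence.
Bootstrap refits quantify ordering stability.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import BiomarkerSpec, STUDY_BATTERY, battery_names
from .exceptions import CogebmError, ConfigurationError, DegenerateDataError
from .mixture import MixtureFit, fit_mixture
from .ordering import (
    EventSequence,
    ProbabilityMatrix,
    SequenceSamples,
    greedy_ascent,
    mcmc_sample,
)
from .preprocessing import ResidualModel, preprocess
from .staging import stage_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tuning knobs for the full fit; defaults match the study-scale run."""

    coding: str = "ordinal"
    stage_prior: bool = True
    clip: float = 1e-12

    # mixture refinement
    mixture_max_iter: int = 200
    mixture_tol: float = 1e-4
    hard_assignment: bool = False
    check_direction: bool = True
    min_group: int = 10

    # sequence optimization
    greedy_starts: int = 4
    mcmc_iters: int = 100_000
    burn_in: int = 10_000

    # bootstrap refits use a lighter search per replicate
    bootstrap_greedy_starts: int = 2
    bootstrap_mcmc_iters: int = 2_000
    bootstrap_stratified: bool = True
    bootstrap_max_retry_frac: float = 0.2

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ModelFit:
    """Everything produced by one full fit."""

    residual_model: ResidualModel
    residualized: pd.DataFrame
    mixtures: dict[str, MixtureFit]
    probabilities: ProbabilityMatrix
    ml_sequence: EventSequence
    log_likelihood: float
    mcmc_samples: SequenceSamples | None = None
    stages: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def fit_all_mixtures(
    residualized: pd.DataFrame,
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
    config: PipelineConfig | None = None,
) -> dict[str, MixtureFit]:
    """Fit one two-component KDE mixture per biomarker on residual scores."""
    config = config or PipelineConfig()
    fits: dict[str, MixtureFit] = {}
    for spec in battery:
        values = residualized[spec.name].to_numpy(float)
        labels = residualized["age_group"].to_numpy()
        keep = ~np.isnan(values)
        fits[spec.name] = fit_mixture(
            values[keep],
            labels[keep],
            spec.decline_direction,
            biomarker=spec.name,
            min_group=config.min_group,
            max_iter=config.mixture_max_iter,
            tol=config.mixture_tol,
            hard_assignment=config.hard_assignment,
            check_direction=config.check_direction,
        )
    return fits


def build_probability_matrix(
    residualized: pd.DataFrame,
    fits: Mapping[str, MixtureFit],
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
    clip: float = 1e-12,
) -> ProbabilityMatrix:
    """Evaluate P(x|E) and P(x|not-E) for every participant and biomarker.

    Missing scores contribute the equal uninformative pair; densities are
    clipped below at ``clip`` so log-space products stay finite.
    """
    names = battery_names(battery)
    n = len(residualized)
    p_e = np.empty((n, len(names)))
    p_ne = np.empty((n, len(names)))
    for i, name in enumerate(names):
        fit = fits[name]
        x = residualized[name].to_numpy(float)
        missing = np.isnan(x)
        xe = np.where(missing, fit.grid[0], x)
        p_e[:, i] = np.interp(xe, fit.grid, fit.event_density)
        p_ne[:, i] = np.interp(xe, fit.grid, fit.nonevent_density)
        p_e[missing, i] = 0.5
        p_ne[missing, i] = 0.5
    return ProbabilityMatrix(
        pE=np.clip(p_e, clip, None),
        pnE=np.clip(p_ne, clip, None),
        biomarker_names=tuple(names),
        participant_ids=tuple(residualized["participant_id"].astype(str)),
    )


def fit_model(
    cohort: pd.DataFrame,
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
    config: PipelineConfig | None = None,
    seed: int | None = 0,
    run_mcmc: bool = True,
    stage: bool = True,
) -> ModelFit:
    """Run the full analysis on one cohort table."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    residualized, residual_model = preprocess(cohort, battery, coding=config.coding)
    logger.info("preprocessed %d participants", len(residualized))
    fits = fit_all_mixtures(residualized, battery, config)
    P = build_probability_matrix(residualized, fits, battery, clip=config.clip)

    s_greedy, ll_greedy = greedy_ascent(
        P, n_starts=config.greedy_starts, seed=rng, stage_prior=config.stage_prior
    )
    samples = None
    s_hat, ll_hat = s_greedy, ll_greedy
    if run_mcmc and config.mcmc_iters > 0:
        samples = mcmc_sample(
            P,
            s_greedy,
            n_iter=config.mcmc_iters,
            burn_in=min(config.burn_in, config.mcmc_iters - 1),
            seed=rng,
            stage_prior=config.stage_prior,
        )
        best = samples.extra.get("best_log_likelihood", -np.inf)
        if best > ll_hat:
            s_hat, ll_hat = samples.ml_sequence, best
        logger.info("MCMC acceptance rate %.3f", samples.acceptance_rate)

    result = ModelFit(
        residual_model=residual_model,
        residualized=residualized,
        mixtures=fits,
        probabilities=P,
        ml_sequence=s_hat,
        log_likelihood=ll_hat,
        mcmc_samples=samples,
        diagnostics={
            "greedy_log_likelihood": ll_greedy,
            "n_participants": len(residualized),
        },
    )
    if stage:
        result.stages = stage_cohort(P, s_hat)
    return result


def sequence_names(fit_or_sequence, names: Sequence[str]) -> list[str]:
    """Translate an index sequence into biomarker names, earliest first."""
    seq = (
        fit_or_sequence.ml_sequence
        if isinstance(fit_or_sequence, ModelFit)
        else fit_or_sequence
    )
    return [names[i] for i in seq.order]


def _resample_indices(
    cohort: pd.DataFrame, stratified: bool, rng: np.random.Generator
) -> np.ndarray:
    if not stratified:
        return rng.integers(0, len(cohort), size=len(cohort))
    parts = []
    for group in ("YA", "OA"):
        idx = np.flatnonzero((cohort["age_group"] == group).to_numpy())
        if idx.size:
            parts.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(parts)


def bootstrap_orderings(
    cohort: pd.DataFrame,
    n_boot: int = 100,
    seed: int | None = 0,
    battery: Sequence[BiomarkerSpec] | None = None,
    config: PipelineConfig | None = None,
    resample: bool = True,
) -> SequenceSamples:
    """Bootstrap the full fit and collect each replicate's best sequence.

    Participants are resampled with replacement (stratified by age group by
    default) and the whole pipeline — residualization, mixture fitting,
    greedy ascent plus a short MCMC — is re-run per replicate.  Replicates
    that fail on degenerate data are retried with a fresh resample; more
    than ``bootstrap_max_retry_frac * n_boot`` retries aborts.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    battery = tuple(battery) if battery is not None else STUDY_BATTERY
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    max_retries = max(1, int(np.ceil(config.bootstrap_max_retry_frac * n_boot)))

    orders: list[np.ndarray] = []
    lls: list[float] = []
    retries = 0
    while len(orders) < n_boot:
        if resample:
            idx = _resample_indices(cohort, config.bootstrap_stratified, rng)
            replicate = cohort.iloc[idx].reset_index(drop=True)
            replicate["participant_id"] = [
                f"B{i:04d}" for i in range(len(replicate))
            ]
        else:
            replicate = cohort
        try:
            residualized, _ = preprocess(replicate, battery, coding=config.coding)
            fits = fit_all_mixtures(residualized, battery, config)
            P = build_probability_matrix(residualized, fits, battery, config.clip)
            s_best, ll_best = greedy_ascent(
                P,
                n_starts=config.bootstrap_greedy_starts,
                seed=rng,
                stage_prior=config.stage_prior,
            )
            if config.bootstrap_mcmc_iters > 0:
                chain = mcmc_sample(
                    P,
                    s_best,
                    n_iter=config.bootstrap_mcmc_iters,
                    seed=rng,
                    stage_prior=config.stage_prior,
                )
                best = chain.extra.get("best_log_likelihood", -np.inf)
                if best > ll_best:
                    s_best, ll_best = chain.ml_sequence, best
        except (DegenerateDataError, CogebmError) as exc:
            retries += 1
            logger.warning("bootstrap replicate failed (%s); retrying", exc)
            if retries > max_retries:
                raise CogebmError(
                    f"too many degenerate bootstrap replicates ({retries})"
                ) from exc
            continue
        orders.append(s_best.as_array())
        lls.append(ll_best)

    lls_arr = np.asarray(lls)
    best_idx = int(np.argmax(lls_arr))
    return SequenceSamples(
        sequences=np.stack(orders),
        log_likelihoods=lls_arr,
        kind="bootstrap",
        ml_sequence=EventSequence(tuple(int(i) for i in orders[best_idx])),
        extra={"n_retries": retries},
    )
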