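"""Shared fixtures: fast pipeline settings and reusable study-scale runs."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from cogebm.battery import battery_names
from cogebm.pipeline import PipelineConfig, fit_model
from cogebm.synthetic import CohortConfig, GroundTruth, generate_cohort

STUDY_SEEDS = tuple(range(1, 11))


def strong_cohort_config(seed: int) -> CohortConfig:
    """Study-sized cohort with strong pre/post separation and shifted APOE4
    stages, used for the model-validity checks."""
    return CohortConfig(seed=seed, noise_scale=0.4, apoe4_stage_shift=8)


@pytest.fixture(scope="session")
def fast_pipeline_config() -> PipelineConfig:
    """Reduced search effort; enough for well-separated synthetic data."""
    return PipelineConfig(
        greedy_starts=2,
        mcmc_iters=3000,
        burn_in=300,
        bootstrap_greedy_starts=2,
        bootstrap_mcmc_iters=1000,
    )


@dataclass
class StudyRun:
    seed: int
    cohort: pd.DataFrame
    truth: GroundTruth
    fit: object  # ModelFit

    @property
    def true_positions(self) -> list[int]:
        return [self.truth.sequence.index(n) for n in battery_names()]

    @property
    def recovered_positions(self) -> np.ndarray:
        pos = np.empty(len(self.truth.sequence), dtype=int)
        pos[list(self.fit.ml_sequence.order)] = np.arange(pos.size)
        return pos

    @property
    def true_stages(self) -> np.ndarray:
        ids = self.fit.stages["participant_id"]
        return np.array([self.truth.stage_of[p] for p in ids])


@pytest.fixture(scope="session")
def study_runs(fast_pipeline_config) -> list[StudyRun]:
    """Ten full pipeline fits on strong-separation study-sized cohorts."""
    runs = []
    for seed in STUDY_SEEDS:
        cohort, truth = generate_cohort(strong_cohort_config(seed))
        fit = fit_model(cohort, config=fast_pipeline_config, seed=seed)
        runs.append(StudyRun(seed=seed, cohort=cohort, truth=truth, fit=fit))
    return runs
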