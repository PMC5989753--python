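"""Synthetic cohort generation with a known ground-truth event ordering.

Generates participant tables with the statistical structure the downstream
analysis assumes: a young-adult (YA, 16-35) control group concentrated at
stage 0, an older-adult (OA, >=36) disease group spread across stages, a
latent true ordering of biomarker "events", pre/post-event score
distributions per biomarker (bound-censored Gaussians so floor and ceiling
pile-ups emerge naturally), intellectual-disability (ID) level offsets on
direct tests, task non-engagement, and missingness.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import (
    BiomarkerSpec,
    DECREASING,
    DIRECT_TEST,
    STUDY_BATTERY,
    battery_names,
    validate_battery,
)
from .exceptions import ConfigurationError

ID_LEVELS = ("mild", "moderate", "severe")
APOE_GROUPS = ("APOE2", "APOE3", "APOE4", "APOE24", "unknown")
ENGAGEMENT_STATES = ("completed", "attempted_not_understood", "not_attempted")

DEMOGRAPHIC_COLUMNS = (
    "participant_id",
    "age",
    "age_group",
    "sex",
    "id_level",
    "dementia",
    "apoe_group",
)

#: Per-biomarker group summary statistics (mean, SD) for the pre-decline YA
#: group and the mixed OA group, used only to place default generator
#: locations and spreads on a realistic scale.
_CALIBRATION: dict[str, tuple[float, float, float, float]] = {
    "kbit_verbal": (34.95, 16.99, 23.02, 18.77),
    "kbit_nonverbal": (15.00, 6.94, 9.78, 7.43),
    "pal_first_trial_memory": (10.19, 5.67, 4.53, 5.61),
    "immediate_object_memory": (10.26, 3.00, 6.41, 4.75),
    "delayed_object_memory": (5.78, 1.52, 3.60, 2.66),
    "orientation": (9.55, 3.56, 6.52, 4.71),
    "ied_stages_completed": (6.52, 2.59, 3.41, 3.06),
    "tower_of_london": (7.24, 3.12, 4.41, 3.97),
    "verbal_fluency": (10.81, 5.91, 6.10, 5.92),
    "srt_mean_latency": (695.72, 455.97, 1423.08, 793.61),
    "finger_nose_pointing": (11.02, 5.25, 6.09, 5.48),
    "nepsy_visuomotor": (17.12, 9.56, 8.05, 8.91),
    "abs_total": (79.60, 19.46, 64.79, 27.00),
    "dld_cognitive": (7.57, 8.35, 15.68, 12.75),
    "dld_social": (9.31, 6.87, 14.66, 10.52),
    "omq_revised": (43.42, 12.31, 56.38, 17.16),
}


@dataclass
class CohortConfig:
    """Generation parameters for :func:`generate_cohort`.

    The defaults produce a cohort loosely matching the demographic makeup
    and group-level score statistics of the study population (n_ya=119,
    n_oa=164). ``separation`` scales the pre-to-post event location shift;
    ``noise_scale`` scales all score spreads — together they control how
    separable normal and abnormal score distributions are.
    """

    n_ya: int = 119
    n_oa: int = 164
    seed: int = 0

    separation: float = 1.25
    noise_scale: float = 1.0

    # stage distributions
    ya_leak: float = 0.03          # probability a YA participant is past stage 0
    ya_leak_max_stage: int = 2
    oa_stage_probs: tuple[float, ...] | None = None  # default uniform over 0..I
    apoe4_stage_shift: int = 3     # later stages for OA e4 carriers

    # clinical labels
    dementia_midpoint: float = 11.0  # logistic P(dementia | stage) for OA rows
    dementia_steepness: float = 1.5

    # missingness / engagement
    not_understood_rate: float = 0.02
    not_attempted_rate: float = 0.02
    informant_missing_rate: float = 0.05

    # demographics
    id_level_probs_ya: tuple[float, float, float] = (0.38, 0.53, 0.09)
    id_level_probs_oa: tuple[float, float, float] = (0.42, 0.41, 0.17)
    apoe_probs: tuple[float, float, float, float, float] = (0.15, 0.52, 0.24, 0.02, 0.07)

    # additive ID-level shifts on direct tests, in units of the biomarker's
    # pre-event SD; sign is flipped for increasing-direction biomarkers
    id_offset_sd_units: Mapping[str, float] = field(
        default_factory=lambda: {"mild": 0.5, "moderate": 0.0, "severe": -1.0}
    )

    true_sequence: tuple[str, ...] | None = None  # fixed ordering, else random

    def validate(self, battery: Sequence[BiomarkerSpec]) -> None:
        if self.n_ya < 1 or self.n_oa < 1:
            raise ConfigurationError("n_ya and n_oa must be >= 1")
        for name in ("separation", "noise_scale"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        rates = {
            "ya_leak": self.ya_leak,
            "not_understood_rate": self.not_understood_rate,
            "not_attempted_rate": self.not_attempted_rate,
            "informant_missing_rate": self.informant_missing_rate,
        }
        for name, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {rate}")
        for name, probs in (
            ("id_level_probs_ya", self.id_level_probs_ya),
            ("id_level_probs_oa", self.id_level_probs_oa),
            ("apoe_probs", self.apoe_probs),
        ):
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or not math.isclose(arr.sum(), 1.0, abs_tol=1e-6):
                raise ConfigurationError(f"{name} must be nonnegative and sum to 1")
        if set(self.id_offset_sd_units) != set(ID_LEVELS):
            raise ConfigurationError(
                f"id_offset_sd_units must have exactly the keys {ID_LEVELS}"
            )
        if self.oa_stage_probs is not None:
            arr = np.asarray(self.oa_stage_probs, dtype=float)
            n_events = len(battery)
            if arr.size != n_events + 1:
                raise ConfigurationError(
                    f"oa_stage_probs must have length {n_events + 1}"
                )
            if (arr < 0).any() or not math.isclose(arr.sum(), 1.0, abs_tol=1e-6):
                raise ConfigurationError("oa_stage_probs must be a distribution")
        if self.true_sequence is not None:
            if sorted(self.true_sequence) != sorted(battery_names(battery)):
                raise ConfigurationError(
                    "true_sequence must be a permutation of the battery names"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in (
            "oa_stage_probs",
            "true_sequence",
            "id_level_probs_ya",
            "id_level_probs_oa",
            "apoe_probs",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class EventParams:
    """Pre- and post-event score distribution parameters for one biomarker."""

    pre_loc: float
    pre_scale: float
    post_loc: float
    post_scale: float


@dataclass
class GroundTruth:
    """Latent generative state recorded alongside a synthetic cohort."""

    sequence: tuple[str, ...]
    stage_of: dict[str, int]
    event_params: dict[str, EventParams]
    id_level_offsets: dict[str, dict[str, float]]

    def position_of(self, name: str) -> int:
        return self.sequence.index(name)


def default_event_params(
    spec: BiomarkerSpec, separation: float = 1.0, noise_scale: float = 1.0
) -> EventParams:
    """Pre/post-event locations and spreads for one biomarker.

    The pre-event distribution matches the YA group summary; the post-event
    location is placed two group-differences past it (the OA group mixes
    participants before and after each event, so its mean sits roughly
    halfway between the two components).
    """
    ya_mean, ya_sd, oa_mean, oa_sd = _CALIBRATION[spec.name]
    shift = 2.0 * (oa_mean - ya_mean) * separation
    return EventParams(
        pre_loc=ya_mean,
        pre_scale=ya_sd * noise_scale,
        post_loc=ya_mean + shift,
        post_scale=oa_sd * noise_scale,
    )


def _sample_stages(cfg: CohortConfig, n_events: int, apoe: np.ndarray,
                   age_group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = age_group.size
    stages = np.zeros(n, dtype=int)
    ya = age_group == "YA"
    # YA: concentrated at 0 with a configurable leak into early stages
    leak = rng.random(n) < cfg.ya_leak
    leak_stage = rng.integers(1, max(cfg.ya_leak_max_stage, 1) + 1, size=n)
    stages[ya & leak] = leak_stage[ya & leak]
    # OA: configurable distribution over 0..I, default uniform
    oa = ~ya
    if cfg.oa_stage_probs is None:
        oa_draw = rng.integers(0, n_events + 1, size=n)
    else:
        oa_draw = rng.choice(n_events + 1, size=n, p=np.asarray(cfg.oa_stage_probs))
    stages[oa] = oa_draw[oa]
    shifted = oa & (apoe == "APOE4")
    stages[shifted] = np.minimum(n_events, stages[shifted] + cfg.apoe4_stage_shift)
    return stages


def generate_cohort(
    config: CohortConfig,
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort table plus its generative ground truth.

    Returns a dataframe with one row per participant (demographics, one
    score column per biomarker, one ``<name>__engagement`` column per
    biomarker) and a :class:`GroundTruth` holding the latent ordering,
    per-participant stages and distribution parameters.  Identical config
    and seed produce bitwise-identical outputs.
    """
    validate_battery(battery)
    config.validate(battery)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    names = battery_names(battery)
    n_events = len(battery)
    n = config.n_ya + config.n_oa

    if config.true_sequence is not None:
        sequence = tuple(config.true_sequence)
    else:
        sequence = tuple(names[i] for i in rng.permutation(n_events))
    position = {name: sequence.index(name) for name in names}

    age_group = np.array(["YA"] * config.n_ya + ["OA"] * config.n_oa)
    age = np.where(
        age_group == "YA",
        np.clip(rng.normal(25.24, 5.58, size=n), 16.0, 35.0),
        np.clip(rng.normal(49.58, 7.47, size=n), 36.0, 75.0),
    ).round(1)
    sex = rng.choice(["M", "F"], size=n)
    id_level = np.empty(n, dtype=object)
    ya_mask = age_group == "YA"
    id_level[ya_mask] = rng.choice(
        ID_LEVELS, size=int(ya_mask.sum()), p=config.id_level_probs_ya
    )
    id_level[~ya_mask] = rng.choice(
        ID_LEVELS, size=int((~ya_mask).sum()), p=config.id_level_probs_oa
    )
    apoe = rng.choice(APOE_GROUPS, size=n, p=config.apoe_probs)

    stages = _sample_stages(config, n_events, apoe, age_group, rng)

    # dementia only arises in the OA group, with probability rising along stage
    logits = (stages - config.dementia_midpoint) / max(config.dementia_steepness, 1e-9)
    p_dem = 1.0 / (1.0 + np.exp(-logits))
    dementia = np.where(
        (age_group == "OA") & (rng.random(n) < p_dem), "diagnosed", "none"
    )

    event_params: dict[str, EventParams] = {}
    id_offsets: dict[str, dict[str, float]] = {}
    for spec in battery:
        params = default_event_params(spec, config.separation, config.noise_scale)
        event_params[spec.name] = params
        sign = 1.0 if spec.decline_direction == DECREASING else -1.0
        if spec.modality == DIRECT_TEST:
            # offsets scale with the pre-event spread, so degenerate-noise
            # configs collapse scores exactly onto the event locations
            id_offsets[spec.name] = {
                level: sign * config.id_offset_sd_units[level] * params.pre_scale
                for level in ID_LEVELS
            }
        else:
            id_offsets[spec.name] = {level: 0.0 for level in ID_LEVELS}

    participant_id = np.array([f"P{i:04d}" for i in range(n)])
    data: dict[str, np.ndarray] = {
        "participant_id": participant_id,
        "age": age,
        "age_group": age_group,
        "sex": sex,
        "id_level": id_level,
        "dementia": dementia,
        "apoe_group": apoe,
    }

    level_codes = np.array([ID_LEVELS.index(lv) for lv in id_level])
    for spec in battery:
        params = event_params[spec.name]
        past_event = position[spec.name] < stages  # stage k => first k events done
        loc = np.where(past_event, params.post_loc, params.pre_loc)
        scale = np.where(past_event, params.post_scale, params.pre_scale)
        offsets = np.array([id_offsets[spec.name][lv] for lv in ID_LEVELS])
        raw = loc + offsets[level_codes] + rng.standard_normal(n) * scale
        if spec.integer_valued:
            raw = np.round(raw)
        scores = np.clip(raw, spec.score_min, spec.score_max)

        engagement = np.full(n, "completed", dtype=object)
        if spec.modality == DIRECT_TEST:
            u = rng.random(n)
            not_understood = u < config.not_understood_rate
            not_attempted = (u >= config.not_understood_rate) & (
                u < config.not_understood_rate + config.not_attempted_rate
            )
            engagement[not_understood] = "attempted_not_understood"
            engagement[not_attempted] = "not_attempted"
            scores = np.where(engagement == "completed", scores, np.nan)
        else:
            missing = rng.random(n) < config.informant_missing_rate
            engagement[missing] = "not_attempted"
            scores = np.where(missing, np.nan, scores)

        data[spec.name] = scores
        data[f"{spec.name}__engagement"] = engagement

    cohort = pd.DataFrame(data)
    truth = GroundTruth(
        sequence=sequence,
        stage_of=dict(zip(participant_id.tolist(), stages.tolist())),
        event_params=event_params,
        id_level_offsets=id_offsets,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# plain-text IO


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV with ``NA`` for missing scores."""
    cohort.to_csv(path, index=False, na_rep="NA")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "sequence": list(truth.sequence),
        "stage_of": truth.stage_of,
        "event_params": {k: asdict(v) for k, v in truth.event_params.items()},
        "id_level_offsets": truth.id_level_offsets,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        sequence=tuple(payload["sequence"]),
        stage_of={k: int(v) for k, v in payload["stage_of"].items()},
        event_params={
            k: EventParams(**v) for k, v in payload["event_params"].items()
        },
        id_level_offsets=payload["id_level_offsets"],
    )
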