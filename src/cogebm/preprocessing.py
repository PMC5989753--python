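"""Imputation rules and ID-level residualization.

Two imputation rules operate before modelling:

* participants who attempted a task but could not understand the
  instructions receive a score of zero — except for mean reaction-time
  latency, where the poorest (largest) latency recorded in the cohort is
  given instead;
* missing questionnaire items are imputed with the nearest integer to the
  mean of completed items, for up to a configurable fraction (default 15%)
  of items per domain; beyond that the domain total is treated as missing.

Residualization then removes baseline-ability differences: a per-biomarker
linear regression of score on intellectual-disability (ID) level is fitted
on the young-adult (YA) rows only, and its predictions are subtracted from
every participant's scores.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .battery import BiomarkerSpec, STUDY_BATTERY, battery_names
from .exceptions import ConfigurationError, PreprocessingError

logger = logging.getLogger(__name__)

#: Ordinal severity coding used in the default regression design.
ID_LEVEL_CODES = {"mild": 1.0, "moderate": 2.0, "severe": 3.0}

SRT_BIOMARKER = "srt_mean_latency"


def impute_performance_scores(
    cohort: pd.DataFrame, battery: Sequence[BiomarkerSpec] = STUDY_BATTERY
) -> pd.DataFrame:
    """Fill scores for tasks that were attempted but not understood.

    Such attempts score zero on every outcome except ``srt_mean_latency``,
    which receives the worst (maximum) completed latency in the cohort.
    ``not_attempted`` rows stay missing; completed scores are untouched.
    """
    out = cohort.copy()
    for spec in battery:
        flag_col = f"{spec.name}__engagement"
        if flag_col not in out.columns:
            raise PreprocessingError(f"missing engagement column {flag_col!r}")
        not_understood = out[flag_col] == "attempted_not_understood"
        if not not_understood.any():
            continue
        if spec.name == SRT_BIOMARKER:
            completed = out.loc[out[flag_col] == "completed", spec.name].dropna()
            if completed.empty:
                raise PreprocessingError(
                    "cannot impute srt_mean_latency: no completed latencies recorded"
                )
            fill = float(completed.max())
        else:
            fill = 0.0
        out.loc[not_understood, spec.name] = fill
    return out


def impute_questionnaire_items(
    item_scores: Sequence[float], max_missing_frac: float = 0.15
) -> np.ndarray | None:
    """Impute missing questionnaire items from the completed-item mean.

    Each missing item is replaced by the nearest integer (ties round half
    away from zero) to the mean of the completed items, provided the missing
    fraction does not exceed ``max_missing_frac``.  Returns ``None`` when
    the domain must be treated as missing (too many missing items, or no
    completed items at all).  Completed items are never altered.
    """
    if not 0.0 < max_missing_frac <= 1.0:
        raise ConfigurationError("max_missing_frac must lie in (0, 1]")
    items = np.asarray(item_scores, dtype=float)
    if items.size == 0:
        raise ConfigurationError("item_scores is empty")
    missing = np.isnan(items)
    if not missing.any():
        return items.copy()
    if missing.all():
        return None
    if missing.mean() > max_missing_frac:
        return None
    mean = float(items[~missing].mean())
    fill = math.floor(abs(mean) + 0.5) * (1 if mean >= 0 else -1)
    out = items.copy()
    out[missing] = float(fill)
    return out


@dataclass
class ResidualModel:
    """Per-biomarker linear fits of score on ID level, YA rows only."""

    coding: str  # "ordinal" | "dummy"
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    fitted_on: str = "YA"

    def predict(self, biomarker: str, id_level: str) -> float:
        if id_level not in ID_LEVEL_CODES:
            raise PreprocessingError(f"unknown ID level {id_level!r}")
        beta = self.coefficients[biomarker]
        return float(self._design_row(id_level) @ beta)

    def _design_row(self, id_level: str) -> np.ndarray:
        if self.coding == "ordinal":
            return np.array([1.0, ID_LEVEL_CODES[id_level]])
        return np.array(
            [1.0, float(id_level == "moderate"), float(id_level == "severe")]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coding": self.coding,
            "fitted_on": self.fitted_on,
            "coefficients": {k: v.tolist() for k, v in self.coefficients.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResidualModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coding=payload["coding"],
            fitted_on=payload["fitted_on"],
            coefficients={
                k: np.asarray(v, dtype=float)
                for k, v in payload["coefficients"].items()
            },
        )


def fit_residual_model(
    cohort: pd.DataFrame,
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
    coding: str = "ordinal",
) -> ResidualModel:
    """Least-squares fit of each biomarker's score on ID level, using YA rows.

    Ordinal coding (mild=1, moderate=2, severe=3) is the default; ``dummy``
    switches to treatment coding with mild as reference.
    """
    if coding not in ("ordinal", "dummy"):
        raise ConfigurationError(f"unknown coding {coding!r}")
    model = ResidualModel(coding=coding)
    ya = cohort[cohort["age_group"] == "YA"]
    for name in battery_names(battery):
        rows = ya[ya[name].notna() & ya["id_level"].isin(ID_LEVEL_CODES)]
        if len(rows) < 3:
            raise PreprocessingError(
                f"biomarker {name!r}: only {len(rows)} usable YA rows (need >= 3)"
            )
        if rows["id_level"].nunique() < 2:
            raise PreprocessingError(
                f"biomarker {name!r}: need >= 2 distinct ID levels among YA rows"
            )
        design = np.stack([model._design_row(lv) for lv in rows["id_level"]])
        beta, *_ = np.linalg.lstsq(design, rows[name].to_numpy(float), rcond=None)
        model.coefficients[name] = beta
    return model


def residualize(
    cohort: pd.DataFrame,
    model: ResidualModel,
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
) -> pd.DataFrame:
    """Replace every non-missing score by observed minus the YA-fit prediction.

    Applied to YA and OA rows alike; missing scores stay missing.  Rows with
    an unrecognized ID level get missing residuals and a logged warning.
    """
    out = cohort.copy()
    known = cohort["id_level"].isin(ID_LEVEL_CODES)
    if (~known).any():
        logger.warning(
            "%d rows have unknown ID level; their residuals are set missing",
            int((~known).sum()),
        )
    preds = {
        name: np.where(
            known,
            [
                model.predict(name, lv) if lv in ID_LEVEL_CODES else 0.0
                for lv in cohort["id_level"]
            ],
            np.nan,
        )
        for name in battery_names(battery)
    }
    for name, predicted in preds.items():
        out[name] = cohort[name].to_numpy(float) - predicted
    return out


def preprocess(
    cohort: pd.DataFrame,
    battery: Sequence[BiomarkerSpec] = STUDY_BATTERY,
    coding: str = "ordinal",
) -> tuple[pd.DataFrame, ResidualModel]:
    """Performance-score imputation followed by ID-level residualization."""
    imputed = impute_performance_scores(cohort, battery)
    model = fit_residual_model(imputed, battery, coding=coding)
    return residualize(imputed, model, battery), model
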