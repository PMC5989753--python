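"""The 16-outcome cognitive and informant test battery.

Each outcome ("biomarker" in event-based-model terminology) carries its valid
score range, the direction in which scores move as ability declines, whether
it is measured directly on the participant or via an informant questionnaire,
and whether scores are integer valued.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import ConfigurationError

DECREASING = "decreasing"
INCREASING = "increasing"
DIRECT_TEST = "direct_test"
INFORMANT = "informant"

_DIRECTIONS = frozenset({DECREASING, INCREASING})
_MODALITIES = frozenset({DIRECT_TEST, INFORMANT})


@dataclass(frozen=True)
class BiomarkerSpec:
    """Static description of one test outcome.

    Parameters
    ----------
    name : str
        Identifier used in cohort tables and model outputs.
    score_min, score_max : float
        Valid score range; ``score_max`` may be ``math.inf`` for open-ended
        outcomes (e.g. counts without a ceiling, reaction-time latencies).
    decline_direction : {"decreasing", "increasing"}
        Direction scores move as the measured ability deteriorates.
    modality : {"direct_test", "informant"}
        Whether the participant performs the task or an informant rates them.
    integer_valued : bool
        True for discrete scores (rounded on generation).
    """

    name: str
    score_min: float
    score_max: float
    decline_direction: str
    modality: str
    integer_valued: bool = True

    def __post_init__(self) -> None:
        if self.decline_direction not in _DIRECTIONS:
            raise ConfigurationError(
                f"{self.name}: decline_direction must be one of {sorted(_DIRECTIONS)}"
            )
        if self.modality not in _MODALITIES:
            raise ConfigurationError(
                f"{self.name}: modality must be one of {sorted(_MODALITIES)}"
            )
        if math.isfinite(self.score_max) and not self.score_min < self.score_max:
            raise ConfigurationError(f"{self.name}: score_min must be < score_max")

    @property
    def bounded_above(self) -> bool:
        return math.isfinite(self.score_max)

    def clip(self, value: float) -> float:
        """Round (if integer valued) and clamp a raw value into the range."""
        if self.integer_valued:
            value = float(round(value))
        return min(max(value, self.score_min), self.score_max)


#: The full study battery: 11 direct cognitive outcomes, orientation, and
#: 4 informant questionnaire outcomes.  Scores decline downward for all
#: outcomes except reaction-time latency and the three deficit-counting
#: questionnaires, which rise with deterioration.
STUDY_BATTERY: tuple[BiomarkerSpec, ...] = (
    BiomarkerSpec("kbit_verbal", 0, 108, DECREASING, DIRECT_TEST),
    BiomarkerSpec("kbit_nonverbal", 0, 46, DECREASING, DIRECT_TEST),
    BiomarkerSpec("pal_first_trial_memory", 0, 26, DECREASING, DIRECT_TEST),
    BiomarkerSpec("immediate_object_memory", 0, 14, DECREASING, DIRECT_TEST),
    BiomarkerSpec("delayed_object_memory", 0, 7, DECREASING, DIRECT_TEST),
    BiomarkerSpec("orientation", 0, 12, DECREASING, DIRECT_TEST),
    BiomarkerSpec("ied_stages_completed", 0, 9, DECREASING, DIRECT_TEST),
    BiomarkerSpec("tower_of_london", 0, 10, DECREASING, DIRECT_TEST),
    BiomarkerSpec("verbal_fluency", 0, math.inf, DECREASING, DIRECT_TEST),
    BiomarkerSpec(
        "srt_mean_latency", 0, math.inf, INCREASING, DIRECT_TEST, integer_valued=False
    ),
    BiomarkerSpec("finger_nose_pointing", 0, math.inf, DECREASING, DIRECT_TEST),
    BiomarkerSpec("nepsy_visuomotor", 0, 52, DECREASING, DIRECT_TEST),
    BiomarkerSpec("abs_total", 0, 113, DECREASING, INFORMANT),
    BiomarkerSpec("dld_cognitive", 0, 44, INCREASING, INFORMANT),
    BiomarkerSpec("dld_social", 0, 60, INCREASING, INFORMANT),
    BiomarkerSpec("omq_revised", 18, 90, INCREASING, INFORMANT),
)

BATTERY_BY_NAME = {spec.name: spec for spec in STUDY_BATTERY}


def battery_names(battery: Iterable[BiomarkerSpec] = STUDY_BATTERY) -> list[str]:
    return [spec.name for spec in battery]


def validate_battery(battery: Sequence[BiomarkerSpec]) -> None:
    """Check a battery is usable: unique names, at least one biomarker."""
    names = [spec.name for spec in battery]
    if not names:
        raise ConfigurationError("battery is empty")
    if len(set(names)) != len(names):
        raise ConfigurationError("battery contains duplicate biomarker names")
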