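"""Maximum-likelihood disease staging of individual participants.

Given the fitted sequence S, a participant's stage k maximizes

    prod_{i<=k} P(x_{S(i)} | E) * prod_{i>k} P(x_{S(i)} | not-E)

over k = 0..I.  Ties resolve to the smallest stage (conservative: favors
"no decline").  Missing biomarkers contribute equal densities and therefore
do not pull the argmax either way.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .ordering import EventSequence, ProbabilityMatrix, _stage_log_liks


@dataclass
class StageAssignment:
    participant_id: str
    stage: int
    stage_likelihoods: np.ndarray  # length I+1, normalized to sum 1
    flat: bool = False             # True when every stage is equally likely

    def __post_init__(self) -> None:
        lik = np.asarray(self.stage_likelihoods, dtype=float)
        if (lik < 0).any() or abs(lik.sum() - 1.0) > 1e-9:
            raise ConfigurationError("stage_likelihoods must be a distribution")
        self.stage_likelihoods = lik


def stage_participant(
    pE_row: np.ndarray,
    pnE_row: np.ndarray,
    S_hat: EventSequence,
    participant_id: str = "",
) -> StageAssignment:
    """Assign the maximum-likelihood stage for one participant.

    ``pE_row``/``pnE_row`` hold the per-biomarker event / non-event density
    values in battery order; ``S_hat`` is the fitted sequence.
    """
    order = S_hat.as_array()
    log_e = np.log(np.asarray(pE_row, dtype=float)[order])
    log_ne = np.log(np.asarray(pnE_row, dtype=float)[order])
    pre = np.concatenate([[0.0], np.cumsum(log_e)])
    post = np.concatenate([np.cumsum(log_ne[::-1])[::-1], [0.0]])
    log_lik = pre + post
    stage = int(np.argmax(log_lik))  # argmax returns the smallest tied index
    shifted = log_lik - log_lik.max()
    lik = np.exp(shifted)
    lik /= lik.sum()
    flat = bool(np.ptp(log_lik) < 1e-12)
    return StageAssignment(participant_id, stage, lik, flat=flat)


def stage_cohort(P: ProbabilityMatrix, S_hat: EventSequence) -> pd.DataFrame:
    """Stage every participant in a probability matrix.

    Returns a dataframe with ``participant_id``, ``stage``, a ``flat`` flag
    for participants whose likelihood carries no stage information (e.g. all
    biomarkers missing), and the normalized per-stage likelihoods.
    """
    order = S_hat.as_array()
    if order.size != P.n_events:
        raise ConfigurationError("sequence length does not match matrix")
    log_lik = _stage_log_liks(P, order)
    stages = np.argmax(log_lik, axis=1)
    shifted = log_lik - log_lik.max(axis=1, keepdims=True)
    lik = np.exp(shifted)
    lik /= lik.sum(axis=1, keepdims=True)
    flat = np.ptp(log_lik, axis=1) < 1e-12
    out = pd.DataFrame(
        {
            "participant_id": list(P.participant_ids),
            "stage": stages.astype(int),
            "flat": flat,
        }
    )
    for k in range(P.n_events + 1):
        out[f"lik_stage_{k}"] = lik[:, k]
    return out
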