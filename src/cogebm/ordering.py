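"""Maximum-likelihood event ordering.

The model scores a candidate event sequence S by

    P(X | S) = prod_j sum_{k=0}^{I} prod_{i<=k} P(x_{S(i) j} | E) *
                                    prod_{i>k}  P(x_{S(i) j} | not-E)

i.e. each participant's likelihood marginalizes over the I+1 possible
stages along S.  The sequence is optimized by greedy pairwise-swap ascent
from random restarts, followed by Metropolis MCMC over permutations, whose
samples also quantify ordering uncertainty (positional variance diagrams).
All products are taken in log space.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class EventSequence:
    """A permutation of biomarker indices; position 0 is the earliest event."""

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ConfigurationError(
                f"order must be a permutation of 0..{len(self.order) - 1}"
            )

    def __len__(self) -> int:
        return len(self.order)

    def position_of(self, index: int) -> int:
        return self.order.index(index)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.order, dtype=int)


@dataclass
class ProbabilityMatrix:
    """Per-participant, per-biomarker event / non-event density values.

    ``pE[j, i]`` is P(x_ij | E_i) and ``pnE[j, i]`` is P(x_ij | not-E_i);
    entries must be strictly positive (densities are clipped upstream).
    """

    pE: np.ndarray
    pnE: np.ndarray
    biomarker_names: tuple[str, ...]
    participant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.pE = np.asarray(self.pE, dtype=float)
        self.pnE = np.asarray(self.pnE, dtype=float)
        j, i = self.pE.shape
        if self.pnE.shape != (j, i):
            raise ConfigurationError("pE and pnE shapes differ")
        if len(self.biomarker_names) != i or len(self.participant_ids) != j:
            raise ConfigurationError("name lists do not match matrix shape")
        if (self.pE <= 0).any() or (self.pnE <= 0).any():
            raise ConfigurationError("probability entries must be strictly positive")

    @property
    def n_events(self) -> int:
        return self.pE.shape[1]

    @property
    def n_participants(self) -> int:
        return self.pE.shape[0]


@dataclass
class SequenceSamples:
    """A bag of sampled sequences with their log-likelihoods."""

    sequences: np.ndarray          # (n_samples, I) integer matrix
    log_likelihoods: np.ndarray    # (n_samples,)
    kind: str                      # "mcmc" | "bootstrap"
    ml_sequence: EventSequence
    acceptance_rate: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise ConfigurationError("SequenceSamples must be nonempty")
        if len(self.sequences) != len(self.log_likelihoods):
            raise ConfigurationError("every sample needs a recorded likelihood")


def _stage_log_liks(P: ProbabilityMatrix, order: np.ndarray) -> np.ndarray:
    """(J, I+1) matrix of per-participant log-likelihoods at each stage k."""
    log_e = np.log(P.pE[:, order])
    log_ne = np.log(P.pnE[:, order])
    j = log_e.shape[0]
    zeros = np.zeros((j, 1))
    # prefix sums of abnormal terms and suffix sums of normal terms
    pre = np.concatenate([zeros, np.cumsum(log_e, axis=1)], axis=1)
    post = np.concatenate(
        [np.cumsum(log_ne[:, ::-1], axis=1)[:, ::-1], zeros], axis=1
    )
    return pre + post


def sequence_log_likelihood(
    P: ProbabilityMatrix,
    S: EventSequence | Sequence[int],
    stage_prior: bool = True,
) -> float:
    """Total data log-likelihood of an event sequence.

    ``stage_prior`` includes the uniform 1/(I+1) prior over stages; it is a
    constant in S, so argmax-over-sequences results are unaffected either way.
    """
    order = S.as_array() if isinstance(S, EventSequence) else EventSequence(
        tuple(int(i) for i in S)
    ).as_array()
    if order.size != P.n_events:
        raise ConfigurationError("sequence length does not match matrix")
    ll = float(logsumexp(_stage_log_liks(P, order), axis=1).sum())
    if stage_prior:
        ll -= P.n_participants * np.log(P.n_events + 1)
    return ll


def _ll_of_order(P: ProbabilityMatrix, order: np.ndarray, stage_prior: bool) -> float:
    ll = float(logsumexp(_stage_log_liks(P, order), axis=1).sum())
    if stage_prior:
        ll -= P.n_participants * np.log(P.n_events + 1)
    return ll


def greedy_ascent(
    P: ProbabilityMatrix,
    n_starts: int = 4,
    seed: int | np.random.Generator | None = 0,
    stage_prior: bool = True,
) -> tuple[EventSequence, float]:
    """Best-improvement pairwise-swap hill climbing from random restarts.

    From each random starting permutation, the best improving swap of two
    positions is applied until no swap improves the log-likelihood; the best
    sequence over all starts is returned with its log-likelihood.
    """
    if n_starts < 1:
        raise ConfigurationError("n_starts must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    n = P.n_events
    best_order: np.ndarray | None = None
    best_ll = -np.inf
    for _ in range(n_starts):
        order = rng.permutation(n)
        ll = _ll_of_order(P, order, stage_prior)
        improved = True
        while improved:
            improved = False
            sweep_best_ll = ll
            sweep_best: tuple[int, int] | None = None
            for a in range(n - 1):
                for b in range(a + 1, n):
                    order[a], order[b] = order[b], order[a]
                    cand = _ll_of_order(P, order, stage_prior)
                    order[a], order[b] = order[b], order[a]
                    if cand > sweep_best_ll:
                        sweep_best_ll = cand
                        sweep_best = (a, b)
            if sweep_best is not None:
                a, b = sweep_best
                order[a], order[b] = order[b], order[a]
                ll = sweep_best_ll
                improved = True
        if ll > best_ll:
            best_ll = ll
            best_order = order.copy()
    assert best_order is not None
    return EventSequence(tuple(int(i) for i in best_order)), best_ll


def mcmc_sample(
    P: ProbabilityMatrix,
    init: EventSequence,
    n_iter: int = 100_000,
    seed: int | np.random.Generator | None = 0,
    burn_in: int = 0,
    thin: int = 1,
    stage_prior: bool = True,
) -> SequenceSamples:
    """Metropolis sampling over permutations.

    Proposals swap two uniformly chosen positions; acceptance probability is
    min(1, exp(delta log-likelihood)).  The current state is recorded every
    ``thin`` iterations after ``burn_in``, so positional variance reflects
    the visited distribution; the maximum-likelihood state encountered
    anywhere in the chain is also returned.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    if not 0 <= burn_in < n_iter:
        raise ConfigurationError("burn_in must lie in [0, n_iter)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    n = P.n_events
    order = init.as_array().copy()
    ll = _ll_of_order(P, order, stage_prior)
    best_order, best_ll = order.copy(), ll

    kept_orders: list[np.ndarray] = []
    kept_lls: list[float] = []
    n_accept = 0
    pairs = rng.integers(0, n, size=(n_iter, 2))
    unif = rng.random(n_iter)
    for t in range(n_iter):
        a, b = pairs[t]
        if a == b:
            n_accept += 1  # identity proposal: delta = 0, always accepted
        else:
            order[a], order[b] = order[b], order[a]
            cand = _ll_of_order(P, order, stage_prior)
            if cand >= ll or unif[t] < np.exp(cand - ll):
                ll = cand
                n_accept += 1
                if ll > best_ll:
                    best_ll = ll
                    best_order = order.copy()
            else:
                order[a], order[b] = order[b], order[a]
        if t >= burn_in and (t - burn_in) % thin == 0:
            kept_orders.append(order.copy())
            kept_lls.append(ll)
    return SequenceSamples(
        sequences=np.stack(kept_orders),
        log_likelihoods=np.asarray(kept_lls),
        kind="mcmc",
        ml_sequence=EventSequence(tuple(int(i) for i in best_order)),
        acceptance_rate=n_accept / n_iter,
        extra={"best_log_likelihood": best_ll},
    )


def positional_variance(
    samples: SequenceSamples, reference: EventSequence | None = None
) -> np.ndarray:
    """Proportion of samples placing each biomarker at each position.

    Entry (r, p) is the fraction of samples in which the biomarker at rank r
    of the reference sequence (default: the bag's maximum-likelihood
    sequence) occupies position p.  Rows and columns each sum to 1.
    """
    ref = (reference or samples.ml_sequence).as_array()
    seqs = samples.sequences
    n_samples, n = seqs.shape
    # position of each biomarker in each sample
    positions = np.empty_like(seqs)
    rows = np.arange(n_samples)[:, None]
    positions[rows, seqs] = np.arange(n)[None, :]
    matrix = np.zeros((n, n))
    for r, biomarker in enumerate(ref):
        counts = np.bincount(positions[:, biomarker], minlength=n)
        matrix[r] = counts / n_samples
    return matrix


def bootstrap_orderings(
    cohort,
    n_boot: int = 100,
    seed: int | None = 0,
    battery=None,
    config=None,
):
    """Bootstrap the full fit; see :func:`cogebm.pipeline.bootstrap_orderings`.

    Thin wrapper re-exported here so ordering-related entry points live in
    one namespace; the implementation needs preprocessing and mixture
    fitting, which live upstream of this module.
    """
    from .pipeline import bootstrap_orderings as _impl

    return _impl(cohort, n_boot=n_boot, seed=seed, battery=battery, config=config)
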