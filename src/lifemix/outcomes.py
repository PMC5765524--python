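"""Demographic outcomes of an absorbing stage-classified Markov chain.

All quantities derive from the fundamental matrix ``N = (I - U)^{-1}`` of the
transient matrix ``U``: ``N[i, j]`` is the expected number of annual censuses
spent in stage ``i`` before death, for an individual currently in stage ``j``
— *including* the current census, so diagonal entries are at least 1.  With
that convention, life expectancy at fledging is the PB column sum of ``N`` and
"age" means the number of annual steps since fledging.

Conditional first-passage analysis (age at recruitment, age at first success,
inter-breeding intervals) redirects every transition *into* a target set of
stages to a new absorbing "event" state that competes with death, then
conditions the chain on the event happening before death by Bayes-reweighting
the transient matrix with the event-absorption probabilities ``b``:

    U_c[i, j] = U'[i, j] * b[i] / b[j]

(stages with ``b = 0`` are dropped).  Means and variances of the time to the
event are then the longevity statistics of the conditioned chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import STAGES, AbsorbingChain, stage_index

__all__ = [
    "OutcomeMoments",
    "FirstPassageSpec",
    "fundamental_matrix",
    "occupancy_variance",
    "longevity_moments",
    "expected_lro",
    "occupancy_proportions",
    "recruitment_start",
    "first_passage",
    "breeding_interval",
]

#: Linear solves fail below this reciprocal condition number.
_RCOND_MIN = 1e-12


class SingularChainError(np.linalg.LinAlgError):
    """The chain has no (numerically reachable) absorption: (I - U) is singular."""


@dataclass(frozen=True)
class OutcomeMoments:
    """Moments of a demographic outcome, one entry per starting stage.

    ``prob_event`` is the probability that the outcome's defining event occurs
    before death (identically 1 for unconditional outcomes such as longevity);
    ``mean`` and ``variance`` are conditional on the event where relevant.
    ``no_path`` flags starting stages from which the event is unreachable —
    for those, ``prob_event`` is 0 and the conditional moments are reported as
    0.0 with the flag set, never NaN.
    """

    mean: np.ndarray
    variance: np.ndarray
    prob_event: np.ndarray
    stages: tuple[str, ...] = STAGES
    no_path: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.no_path is None:
            object.__setattr__(self, "no_path", np.zeros(len(self.mean), dtype=bool))

    def for_stage(self, stage: int | str) -> tuple[float, float, float]:
        """(mean, variance, prob_event) for one starting stage."""
        j = stage_index(stage)
        return float(self.mean[j]), float(self.variance[j]), float(self.prob_event[j])


def _solve_fundamental(U: np.ndarray, label: str | None = None) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    A = np.eye(n) - U
    # reciprocal condition number in the 1-norm; cheap at these sizes
    try:
        rcond = 1.0 / np.linalg.cond(A, 1)
    except np.linalg.LinAlgError:
        rcond = 0.0
    if not np.isfinite(rcond) or rcond < _RCOND_MIN:
        who = f" for group {label!r}" if label else ""
        raise SingularChainError(
            f"(I - U) is singular or ill-conditioned{who} (rcond={rcond:.2e}); "
            "the chain has no reachable absorbing state (all survival = 1?)"
        )
    return np.linalg.solve(A, np.eye(n))


def fundamental_matrix(U: np.ndarray, label: str | None = None) -> np.ndarray:
    """Expected stage occupancy times ``N = (I - U)^{-1}``.

    Computed by a linear solve with an explicit conditioning check; raises
    :class:`SingularChainError` naming the offending group when the chain
    cannot reach absorption.
    """
    rho = float(np.max(np.abs(np.linalg.eigvals(np.asarray(U, dtype=float)))))
    if rho >= 1.0 - 1e-14:
        who = f" for group {label!r}" if label else ""
        raise SingularChainError(
            f"spectral radius of U is {rho:.6f}{who}; absorption is not certain, "
            "occupancy times are undefined"
        )
    return _solve_fundamental(U, label)


def occupancy_variance(N: np.ndarray) -> np.ndarray:
    """Variance of stage occupancy times: ``V = (2 N_dg - I) N - N∘N``."""
    N = np.asarray(N, dtype=float)
    Ndg = np.diag(np.diag(N))
    V = (2.0 * Ndg - np.eye(N.shape[0])) @ N - N * N
    # clip tiny negative round-off
    return np.where((V < 0) & (V > -1e-9), 0.0, V)


def _longevity_from_N(N: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = N.shape[0]
    ones = np.ones(n)
    mean = ones @ N
    var = ones @ N @ (2.0 * N - np.eye(n)) - mean * mean
    return mean, np.where((var < 0) & (var > -1e-9), 0.0, var)


def longevity_moments(U: np.ndarray, label: str | None = None) -> OutcomeMoments:
    """Mean and variance of longevity (time to death) per starting stage.

    Mean longevity is the column sum of ``N``; the variance follows from the
    second-moment identity for total time to absorption.
    """
    N = fundamental_matrix(U, label)
    mean, var = _longevity_from_N(N)
    return OutcomeMoments(mean=mean, variance=var, prob_event=np.ones(N.shape[0]))


def expected_lro(U: np.ndarray, label: str | None = None) -> OutcomeMoments:
    """Lifetime reproductive output: occupancy of the successful-breeder stage.

    One chick is fledged per successful season, so LRO equals the time spent
    in ``S``: mean is row ``S`` of ``N`` and variance row ``S`` of ``V``.
    """
    N = fundamental_matrix(U, label)
    V = occupancy_variance(N)
    return OutcomeMoments(mean=N[1, :].copy(), variance=V[1, :].copy(),
                          prob_event=np.ones(N.shape[0]))


def occupancy_proportions(U: np.ndarray, start, label: str | None = None) -> np.ndarray:
    """Expected proportion of remaining life spent in each stage.

    ``start`` is a stage (name or index) or a distribution over the four
    stages; for a distribution the columns of ``N`` are mixed before
    normalizing.
    """
    N = fundamental_matrix(U, label)
    start_arr = np.asarray(start)
    if start_arr.ndim == 0 or isinstance(start, str):
        w = np.zeros(4)
        w[stage_index(start)] = 1.0
    else:
        w = np.asarray(start, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("starting distribution must be a non-negative length-4 vector")
        w = w / w.sum()
    occ = N @ w
    return occ / occ.sum()


def recruitment_start(chain: AbsorbingChain) -> np.ndarray:
    """Starting distribution over stages at recruitment for 'adult life' summaries.

    A recruiting pre-breeder lands in ``S`` with probability ``gamma_PB`` and
    in ``F`` otherwise, so adult-lifetime occupancy is computed from the
    distribution ``(0, gamma_PB, 1 - gamma_PB, 0)``.
    """
    if chain.rates is None:
        raise ValueError("chain carries no vital rates; build it with chain_from_rates")
    g1 = float(chain.rates.gamma[0])
    return np.array([0.0, g1, 1.0 - g1, 0.0])


@dataclass(frozen=True)
class FirstPassageSpec:
    """Specification of a first-passage event: entry into any stage in ``target``."""

    target: tuple[str, ...]
    start: str = "PB"

    def __post_init__(self) -> None:
        tgt = tuple(self.target)
        if not tgt:
            raise ValueError("target set must be non-empty")
        for t in tgt:
            stage_index(t)
        stage_index(self.start)
        object.__setattr__(self, "target", tgt)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array(sorted({stage_index(t) for t in self.target}), dtype=int)


def first_passage(U: np.ndarray, M: np.ndarray | None, spec: FirstPassageSpec,
                  label: str | None = None) -> OutcomeMoments:
    """Competing-risk first passage into a set of stages, conditional on the event.

    Every transition into the target set is redirected to a new absorbing
    "event" state competing with death.  Returns, per starting stage, the
    probability the event happens before death and the mean/variance of the
    number of annual steps to the event, conditional on it occurring.  The
    current stage does not count as an event even if it lies in the target:
    only *entries* do, so inter-breeding intervals can start inside a breeding
    stage.
    """
    U = np.asarray(U, dtype=float)
    tgt = spec.target_indices
    Umod = U.copy()
    Umod[tgt, :] = 0.0
    event_row = U[tgt, :].sum(axis=0)

    Nmod = _solve_fundamental(Umod, label)
    b = event_row @ Nmod  # eventual event-absorption probability per stage

    reachable = b > 1e-300
    mean = np.zeros(4)
    var = np.zeros(4)
    no_path = ~reachable
    if reachable.any():
        bR = b[reachable]
        Uc = Umod[np.ix_(reachable, reachable)] * (bR[:, None] / bR[None, :])
        Nc = _solve_fundamental(Uc, label)
        mR, vR = _longevity_from_N(Nc)
        mean[reachable] = mR
        var[reachable] = vR
    return OutcomeMoments(mean=mean, variance=var, prob_event=b.copy(), no_path=no_path)


def breeding_interval(U: np.ndarray, M: np.ndarray | None, from_stage: int | str,
                      target: Sequence[str] = ("S",), label: str | None = None) -> tuple[float, float, float]:
    """Conditional inter-breeding interval from an adult stage.

    Time until the next *successful* breeding event (entry into ``S``),
    conditional on it happening before death — the convention under which the
    per-stage intervals of the fulmar analysis are recovered; pass
    ``target=("S", "F")`` to time the next breeding attempt instead.
    Returns ``(mean, variance, prob_event)``.
    """
    j = stage_index(from_stage)
    if j == 0:
        raise ValueError("breeding intervals are defined for adult stages (S, F, NB)")
    res = first_passage(U, M, FirstPassageSpec(target=tuple(target), start=STAGES[j]), label)
    return res.for_stage(j)
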