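"""Individual-based Monte Carlo simulation of the mixture-of-chains life history.

This module is the independent oracle for the analytic results: it realizes
individual life trajectories by drawing, each year and in this order, survival
(probability sigma of the current stage), then breeding given survival (beta),
then success given breeding (gamma) — and derives the same outcomes the matrix
calculations predict (longevity including the fledging census, LRO as years
spent as a successful breeder, ages of first recruitment/first success).

Randomness is organised for reproducibility and extensibility: a cohort run
uses one root ``SeedSequence``; each individual gets a deterministically
spawned child stream, so enlarging ``n`` extends the cohort without
reshuffling earlier individuals, and identical seeds reproduce identical
tables byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    FAILED,
    NON_BREEDER,
    PRE_BREEDER,
    STAGES,
    SUCCESSFUL,
    MixtureModel,
    StageVitalRates,
)

__all__ = [
    "LifeTrajectory",
    "simulate_individual",
    "simulate_cohort",
    "empirical_summaries",
    "generate_capture_histories",
    "MAX_LIFESPAN",
]

#: Hard cap on simulated lifespans (annual steps); hitting it flags censoring.
MAX_LIFESPAN = 1000

#: Observation code for "not seen" in capture histories (stages are 1..4).
NOT_SEEN = 0


@dataclass(frozen=True)
class LifeTrajectory:
    """One realized life: the annual stage sequence from fledging to death.

    ``stages`` holds one entry per census the individual was alive for,
    starting with the pre-breeder fledging census; ``censored`` marks lives
    truncated at :data:`MAX_LIFESPAN` rather than ended by death.
    """

    group: str
    stages: np.ndarray
    censored: bool = False

    def __post_init__(self) -> None:
        seq = np.asarray(self.stages, dtype=np.int8)
        if seq.size == 0 or seq[0] != PRE_BREEDER:
            raise ValueError("a life trajectory starts at the pre-breeder fledging census")
        object.__setattr__(self, "stages", seq)

    @property
    def longevity(self) -> int:
        """Years of stage occupancy, counting the fledging census as year one."""
        return int(self.stages.size)

    @property
    def lro(self) -> int:
        """Successful breeding events (= chicks fledged) over the lifetime."""
        return int(np.count_nonzero(self.stages == SUCCESSFUL))

    @property
    def age_first_reproduction(self) -> int | None:
        """Age (steps since fledging) at first entry into S or F; None if never."""
        hits = np.flatnonzero((self.stages == SUCCESSFUL) | (self.stages == FAILED))
        return int(hits[0]) if hits.size else None

    @property
    def age_first_success(self) -> int | None:
        """Age at first entry into S; None if never."""
        hits = np.flatnonzero(self.stages == SUCCESSFUL)
        return int(hits[0]) if hits.size else None


def simulate_individual(rates: StageVitalRates, rng: np.random.Generator,
                        max_steps: int = MAX_LIFESPAN) -> LifeTrajectory:
    """Realize one life trajectory under a single group's vital rates."""
    sigma, beta, gamma = rates.sigma, rates.beta, rates.gamma
    stages = [PRE_BREEDER]
    stage = PRE_BREEDER
    # buffered uniforms: at most 3 draws per year
    buf = rng.random(192)
    pos = 0
    censored = False
    while True:
        if len(stages) >= max_steps:
            censored = True
            break
        if pos + 3 > buf.size:
            buf = rng.random(192)
            pos = 0
        if buf[pos] >= sigma[stage]:  # dies before the next census
            pos += 1
            break
        if buf[pos + 1] < beta[stage]:  # survives and breeds
            stage = SUCCESSFUL if buf[pos + 2] < gamma[stage] else FAILED
            pos += 3
        else:  # survives without breeding
            stage = PRE_BREEDER if stage == PRE_BREEDER else NON_BREEDER
            pos += 2
        stages.append(stage)
    return LifeTrajectory(group=rates.label, stages=np.array(stages, dtype=np.int8),
                          censored=censored)


def _trajectory_record(i: int, traj: LifeTrajectory) -> dict:
    afr = traj.age_first_reproduction
    afs = traj.age_first_success
    return {
        "id": i,
        "group": traj.group,
        "longevity": traj.longevity,
        "lro": traj.lro,
        "age_first_repro": np.nan if afr is None else float(afr),
        "age_first_success": np.nan if afs is None else float(afs),
        "recruited": afr is not None,
        "censored": traj.censored,
    }


def simulate_cohort(mixture: MixtureModel, n: int, seed: int,
                    max_steps: int = MAX_LIFESPAN,
                    return_trajectories: bool = False):
    """Simulate ``n`` individuals with group membership drawn i.i.d. from pi.

    Returns an outcome DataFrame (one row per individual); with
    ``return_trajectories=True`` also the list of :class:`LifeTrajectory`.
    Each individual consumes its own spawned RNG stream (first draw assigns
    the group), so results for the first ``m < n`` individuals are independent
    of ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cum_pi = np.cumsum(mixture.pi)
    group_rates = [c.rates for c in mixture.chains]
    if any(r is None for r in group_rates):
        raise ValueError("mixture chains must carry vital rates (use chain_from_rates)")
    children = np.random.SeedSequence(seed).spawn(n)
    records = []
    trajectories = [] if return_trajectories else None
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        k = int(np.searchsorted(cum_pi, rng.random(), side="right"))
        k = min(k, mixture.g - 1)  # guard against cum_pi[-1] < 1 by round-off
        traj = simulate_individual(group_rates[k], rng, max_steps)
        records.append(_trajectory_record(i, traj))
        if trajectories is not None:
            trajectories.append(traj)
    df = pd.DataFrame.from_records(records)
    return (df, trajectories) if return_trajectories else df


def _se_of_variance(x: np.ndarray) -> float:
    """Large-sample standard error of the sample variance (moment-based)."""
    n = x.size
    if n < 4:
        return np.nan
    s2 = x.var(ddof=1)
    m4 = np.mean((x - x.mean()) ** 4)
    inner = m4 - s2 * s2 * (n - 3) / (n - 1)
    return float(np.sqrt(max(inner, 0.0) / n))


def _summaries_for(x: np.ndarray) -> dict:
    n = x.size
    if n == 0:
        return {"n": 0, "mean": np.nan, "var": np.nan, "se_mean": np.nan, "se_var": np.nan}
    mean = float(x.mean())
    var = float(x.var(ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "mean": mean,
        "var": var,
        "se_mean": float(np.sqrt(var / n)) if n > 1 else np.nan,
        "se_var": _se_of_variance(x),
    }


def empirical_summaries(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-group and pooled moments (with standard errors) of the simulated outcomes.

    Conditional outcomes (ages at first reproduction / first success) are
    summarised among the individuals for which the event occurred, matching
    the analytic conditioning; ``prob_recruit`` is the fraction recruiting.
    Scopes with an empty conditional subset carry n=0 and NaN moments.
    """
    if outcomes.empty:
        raise ValueError("outcome table is empty")
    rows = []
    scopes = [("pooled", outcomes)] + [
        (lab, sub) for lab, sub in outcomes.groupby("group", sort=False)
    ]
    for scope, sub in scopes:
        for outcome in ("longevity", "lro"):
            rows.append({"scope": scope, "outcome": outcome,
                         **_summaries_for(sub[outcome].to_numpy(dtype=float))})
        for outcome in ("age_first_repro", "age_first_success"):
            vals = sub[outcome].dropna().to_numpy(dtype=float)
            rows.append({"scope": scope, "outcome": outcome, **_summaries_for(vals)})
        p = float(sub["recruited"].mean())
        rows.append({"scope": scope, "outcome": "prob_recruit", "n": len(sub),
                     "mean": p, "var": p * (1 - p),
                     "se_mean": float(np.sqrt(p * (1 - p) / len(sub))), "se_var": np.nan})
    return pd.DataFrame(rows)


def generate_capture_histories(mixture: MixtureModel, detection, n: int, years: int,
                               seed: int) -> pd.DataFrame:
    """Emulated mark-recapture data: stage-coded sightings with imperfect detection.

    ``detection`` gives per-stage sighting probabilities (length 4, order PB,
    S, F, NB).  Individuals are banded as fledglings, so the first occasion is
    always observed (code 1 = PB); afterwards an alive individual in stage
    ``s`` is recorded as ``s + 1`` with the stage's detection probability and
    as 0 (not seen) otherwise.  Output is wide: one column per occasion
    (``y0..y{years-1}``) plus ``id`` and the true ``group`` label.
    """
    det = np.asarray(detection, dtype=float)
    if det.shape != (4,) or np.any(det < 0) or np.any(det > 1):
        raise ValueError("detection must be 4 per-stage probabilities in [0, 1]")
    if years < 1:
        raise ValueError("years must be >= 1")
    _, trajectories = simulate_cohort(mixture, n, seed, return_trajectories=True)
    det_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 1])))
    table = np.zeros((n, years), dtype=np.int8)
    for i, traj in enumerate(trajectories):
        alive = min(traj.longevity, years)
        seen = det_rng.random(alive) < det[traj.stages[:alive]]
        seen[0] = True  # banding occasion
        table[i, :alive] = np.where(seen, traj.stages[:alive] + 1, NOT_SEEN)
    df = pd.DataFrame(table, columns=[f"y{t}" for t in range(years)])
    df.insert(0, "group", [t.group for t in trajectories])
    df.insert(0, "id", np.arange(n))
    return df
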