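"""Variance decomposition: individual stochasticity vs. latent heterogeneity.

For any demographic outcome xi, the law of total variance over the mixing
distribution pi splits the inter-individual variance exactly into

    V(xi) = E_pi[ V(xi | group) ]  +  V_pi[ E(xi | group) ]
            (within-group;            (between-group;
             individual stochasticity) heterogeneity)

The within component is the variance that a cohort of *identical* individuals
would still exhibit from chance alone; the between component vanishes when
all groups share the same vital rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MixtureModel, stage_index
from .outcomes import (
    FirstPassageSpec,
    expected_lro,
    first_passage,
    longevity_moments,
)

__all__ = ["DecompositionResult", "decompose", "group_moments", "decompose_outcome", "mixture_mean"]

#: Supported outcomes and their aliases.
_OUTCOMES = {
    "longevity": "longevity",
    "lro": "lro",
    "age_first_reproduction": "age_first_reproduction",
    "age_first_repro": "age_first_reproduction",
    "recruitment_age": "age_first_reproduction",
}


@dataclass(frozen=True)
class DecompositionResult:
    """Within/between split of an outcome's variance (units: outcome squared)."""

    within: float
    between: float

    @property
    def total(self) -> float:
        return self.within + self.between

    @property
    def pct_heterogeneity(self) -> float:
        """Percent of the total variance attributable to heterogeneity."""
        return 100.0 * self.between / self.total if self.total > 0 else 0.0


def decompose(pi, group_means, group_vars) -> DecompositionResult:
    """Apply the law of total variance to per-group means and variances."""
    pi = np.asarray(pi, dtype=float)
    m = np.asarray(group_means, dtype=float)
    v = np.asarray(group_vars, dtype=float)
    if not (pi.shape == m.shape == v.shape):
        raise ValueError(f"pi, means and variances must share a length; got {pi.shape}, {m.shape}, {v.shape}")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("pi must be a probability distribution")
    if np.any(v < 0):
        raise ValueError("group variances must be non-negative")
    within = float(pi @ v)
    between = float(pi @ (m - pi @ m) ** 2)
    return DecompositionResult(within=within, between=between)


def group_moments(mixture: MixtureModel, outcome: str, start: int | str = "PB"
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group (means, variances, event probabilities) of one outcome.

    For ``age_first_reproduction`` the moments are conditional on recruiting
    before death; the third return value carries the per-group recruitment
    probabilities (1.0 for unconditional outcomes).
    """
    key = _OUTCOMES.get(outcome.lower())
    if key is None:
        raise ValueError(f"unsupported outcome {outcome!r}; choose from {sorted(set(_OUTCOMES.values()))}")
    j = stage_index(start)
    means, vars_, probs = [], [], []
    for chain in mixture.chains:
        if key == "longevity":
            mom = longevity_moments(chain.U, chain.label)
        elif key == "lro":
            mom = expected_lro(chain.U, chain.label)
        else:
            mom = first_passage(chain.U, chain.M,
                                FirstPassageSpec(target=("S", "F")), chain.label)
            if mom.no_path[j]:
                raise ValueError(
                    f"group {chain.label!r} has no path from {start} to a breeding state; "
                    "conditional age at first reproduction is undefined"
                )
        m, v, p = mom.for_stage(j)
        means.append(m)
        vars_.append(v)
        probs.append(p)
    return np.array(means), np.array(vars_), np.array(probs)


def decompose_outcome(mixture: MixtureModel, outcome: str, start: int | str = "PB",
                      *, condition_weights: bool = False) -> DecompositionResult:
    """Decompose one demographic outcome across the mixture.

    For the conditional outcome (age at first reproduction) the default
    weights each group's event-conditional moments by the *unconditional*
    mixing distribution pi — a group whose members rarely recruit still enters
    with its full fledging weight.  ``condition_weights=True`` instead
    re-weights pi by each group's recruitment probability (the distribution of
    group membership among recruiters).
    """
    means, vars_, probs = group_moments(mixture, outcome, start)
    w = mixture.pi * probs if condition_weights else np.asarray(mixture.pi, dtype=float)
    return decompose(w / w.sum(), means, vars_)


def mixture_mean(mixture: MixtureModel, outcome: str, start: int | str = "PB",
                 *, condition_weights: bool = False) -> float:
    """Pi-weighted mean of the per-group (conditional) outcome means."""
    means, _, probs = group_moments(mixture, outcome, start)
    w = mixture.pi * probs if condition_weights else np.asarray(mixture.pi, dtype=float)
    return float(w @ means / w.sum())
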