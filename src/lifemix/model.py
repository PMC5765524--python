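"""Stage-classified absorbing Markov chains with finite-mixture heterogeneity.

The life cycle is classified into four breeding states observed on an annual
census: pre-breeder (``PB``, has never bred, including the fledgling year),
successful breeder (``S``, raised a chick this season), failed breeder (``F``)
and non-breeder (``NB``, has bred before but skipped this season).  Death is
the (single, by default) absorbing state.

Three stage-specific vital rates drive every transition:

* ``sigma`` -- annual survival probability,
* ``beta``  -- probability of breeding next season, conditional on survival,
* ``gamma`` -- probability of success, conditional on survival and breeding.

The chain is *column-stochastic*: column ``j`` of a transition matrix is the
distribution over destinations for an individual currently in state ``j``, and
population vectors are column vectors.  This orientation is assumed by every
downstream module.

Unobserved (latent, fixed-for-life) heterogeneity is represented as a finite
mixture of such chains: each individual belongs to one of ``g`` groups for
life, with group membership at fledging drawn from a mixing distribution
``pi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STAGES",
    "PRE_BREEDER",
    "SUCCESSFUL",
    "FAILED",
    "NON_BREEDER",
    "StageVitalRates",
    "AbsorbingChain",
    "MixtureModel",
    "build_transient_matrix",
    "build_mortality_matrix",
    "chain_from_rates",
    "read_rates_table",
    "read_config",
    "load_mixture",
    "southern_fulmar",
    "stage_index",
]

#: Canonical stage order; every 4-vector and matrix axis in the package uses it.
STAGES: tuple[str, ...] = ("PB", "S", "F", "NB")

PRE_BREEDER, SUCCESSFUL, FAILED, NON_BREEDER = range(4)

_VITAL_RATES = ("survival", "breeding", "success")

#: Column-sum tolerance for stochasticity checks.
_STOCHASTIC_ATOL = 1e-12


def stage_index(stage: int | str) -> int:
    """Resolve a stage given by name (``"PB"``) or integer index."""
    if isinstance(stage, str):
        try:
            return STAGES.index(stage)
        except ValueError:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None
    i = int(stage)
    if not 0 <= i < len(STAGES):
        raise ValueError(f"stage index {i} out of range 0..{len(STAGES) - 1}")
    return i


def _as_probability_vector(x: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (len(STAGES),):
        raise ValueError(f"{name} must have exactly {len(STAGES)} entries (stages {STAGES}), got shape {a.shape}")
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError(f"{name} entries must lie in [0, 1], got {a.tolist()}")
    return a


@dataclass(frozen=True)
class StageVitalRates:
    """Stage-specific vital rates for one heterogeneity group.

    Parameters
    ----------
    sigma, beta, gamma
        Length-4 probability vectors in the canonical stage order
        ``("PB", "S", "F", "NB")``.
    label
        Group identifier (e.g. ``"UH-2"``).
    """

    sigma: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    label: str = "group"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", _as_probability_vector(self.sigma, "sigma"))
        object.__setattr__(self, "beta", _as_probability_vector(self.beta, "beta"))
        object.__setattr__(self, "gamma", _as_probability_vector(self.gamma, "gamma"))

    def as_frame(self) -> pd.DataFrame:
        """Rates as a tidy DataFrame (vital_rate x stage)."""
        return pd.DataFrame(
            {"survival": self.sigma, "breeding": self.beta, "success": self.gamma},
            index=list(STAGES),
        ).rename_axis("stage")


def build_transient_matrix(rates: StageVitalRates) -> np.ndarray:
    """Assemble the 4x4 transient (survival-and-transition) matrix ``U``.

    Column ``j`` is the from-stage; row ``i`` the to-stage.  A pre-breeder that
    survives without breeding stays a pre-breeder; a surviving adult that does
    not breed becomes a non-breeder; any surviving breeder lands in ``S`` or
    ``F`` according to success.  The pre-breeder stage is never re-entered.
    """
    s, b, g = rates.sigma, rates.beta, rates.gamma
    U = np.zeros((4, 4))
    U[PRE_BREEDER, PRE_BREEDER] = (1.0 - b[0]) * s[0]
    U[SUCCESSFUL, :] = s * b * g
    U[FAILED, :] = s * b * (1.0 - g)
    U[NON_BREEDER, 1:] = (s * (1.0 - b))[1:]
    return U


def build_mortality_matrix(rates: StageVitalRates) -> np.ndarray:
    """Assemble the 1x4 absorption (mortality) matrix ``M``: ``m_j = 1 - sigma_j``."""
    return (1.0 - rates.sigma)[np.newaxis, :]


@dataclass(frozen=True)
class AbsorbingChain:
    """Absorbing Markov chain for one group: transient ``U`` plus absorption ``M``.

    ``P = [[U, 0], [M, I]]`` is the full column-stochastic chain with ``a``
    absorbing states appended after the 4 transient stages.
    """

    U: np.ndarray
    M: np.ndarray
    label: str = "group"
    rates: StageVitalRates | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        if U.shape != (4, 4):
            raise ValueError(f"U must be 4x4, got {U.shape}")
        if M.shape[1] != 4:
            raise ValueError(f"M must have 4 columns, got {M.shape}")
        if np.any(U < 0) or np.any(M < 0):
            raise ValueError("transition probabilities must be non-negative")
        colsums = U.sum(axis=0) + M.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _STOCHASTIC_ATOL):
            raise ValueError(
                f"columns of [U; M] must sum to 1 (got {colsums.tolist()}) for group {self.label!r}"
            )
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "M", M)

    @property
    def n_absorbing(self) -> int:
        return self.M.shape[0]

    @property
    def P(self) -> np.ndarray:
        """Full (4+a)x(4+a) column-stochastic transition matrix."""
        a = self.n_absorbing
        top = np.hstack([self.U, np.zeros((4, a))])
        bottom = np.hstack([self.M, np.eye(a)])
        return np.vstack([top, bottom])

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.U))))


def chain_from_rates(rates: StageVitalRates) -> AbsorbingChain:
    """Build the absorbing chain (death as the single absorbing state)."""
    return AbsorbingChain(
        U=build_transient_matrix(rates),
        M=build_mortality_matrix(rates),
        label=rates.label,
        rates=rates,
    )


@dataclass(frozen=True)
class MixtureModel:
    """Finite mixture of absorbing chains with mixing distribution ``pi``.

    ``pi[k]`` is the probability that a fledgling belongs to group ``k``;
    all chains share the 4-stage state space.
    """

    chains: tuple[AbsorbingChain, ...]
    pi: np.ndarray

    def __post_init__(self) -> None:
        chains = tuple(self.chains)
        if not chains:
            raise ValueError("mixture needs at least one group")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (len(chains),):
            raise ValueError(f"pi must have one entry per group ({len(chains)}), got shape {pi.shape}")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > _STOCHASTIC_ATOL:
            raise ValueError(f"pi must be a probability distribution summing to 1, got {pi.tolist()}")
        object.__setattr__(self, "chains", chains)
        object.__setattr__(self, "pi", pi)

    @property
    def g(self) -> int:
        """Number of heterogeneity groups."""
        return len(self.chains)

    @property
    def s(self) -> int:
        """Number of transient stages (fixed at 4)."""
        return 4

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.chains)

    def chain(self, group: int | str) -> AbsorbingChain:
        if isinstance(group, str):
            try:
                return self.chains[self.labels.index(group)]
            except ValueError:
                raise KeyError(f"no group labelled {group!r}; have {self.labels}") from None
        return self.chains[int(group)]


# ---------------------------------------------------------------------------
# Parameter file IO
# ---------------------------------------------------------------------------

def read_rates_table(source) -> dict[str, StageVitalRates]:
    """Read a vital-rates CSV into per-group :class:`StageVitalRates`.

    Expected columns: ``vital_rate`` (survival/breeding/success), ``stage``
    (PB/S/F/NB) and one column per group.  Missing combinations are rejected
    with a message naming the field.
    """
    df = pd.read_csv(source)
    for col in ("vital_rate", "stage"):
        if col not in df.columns:
            raise ValueError(f"rates table missing required column {col!r}")
    groups = [c for c in df.columns if c not in ("vital_rate", "stage")]
    if not groups:
        raise ValueError("rates table has no group columns")
    out: dict[str, StageVitalRates] = {}
    indexed = df.set_index(["vital_rate", "stage"])
    if indexed.index.duplicated().any():
        dupes = indexed.index[indexed.index.duplicated()].tolist()
        raise ValueError(f"duplicate rate rows: {dupes}")
    for grp in groups:
        vals = {}
        for rate in _VITAL_RATES:
            row = []
            for st in STAGES:
                try:
                    row.append(float(indexed.loc[(rate, st), grp]))
                except KeyError:
                    raise ValueError(f"rates table missing row vital_rate={rate!r}, stage={st!r}") from None
            vals[rate] = row
        out[grp] = StageVitalRates(
            sigma=vals["survival"], beta=vals["breeding"], gamma=vals["success"], label=grp
        )
    return out


def read_config(source) -> dict:
    """Read a YAML/JSON mixture config holding ``pi``, ``groups`` and options."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(source)
    if not isinstance(cfg, Mapping) or "pi" not in cfg:
        raise ValueError("config must be a mapping containing at least 'pi'")
    return dict(cfg)


def load_mixture(rates_source, config_source) -> MixtureModel:
    """Build a :class:`MixtureModel` from a rates CSV and a mixture config."""
    rates = read_rates_table(rates_source)
    cfg = read_config(config_source)
    groups: Iterable[str] = cfg.get("groups", list(rates))
    missing = [grp for grp in groups if grp not in rates]
    if missing:
        raise ValueError(f"config groups {missing} not present in rates table columns {list(rates)}")
    chains = tuple(chain_from_rates(rates[grp]) for grp in groups)
    return MixtureModel(chains=chains, pi=np.asarray(cfg["pi"], dtype=float))


def _data_path(name: str):
    from importlib.resources import files

    return files("lifemix.data").joinpath(name)


def southern_fulmar() -> MixtureModel:
    """The packaged southern-fulmar model: three heterogeneity groups.

    Model-averaged vital rates under ordinary sea-ice conditions for the
    Ile des Petrels colony, with mixing distribution
    ``pi = (0.14, 0.67, 0.19)`` over groups UH-1..UH-3.
    """
    rates = _data_path("southern_fulmar_rates.csv")
    cfg = _data_path("southern_fulmar_config.yaml")
    return load_mixture(rates.open("r"), cfg.open("r"))
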