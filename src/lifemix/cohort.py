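"""Projection of a heterogeneous cohort with block-structured (vec-permutation) matrices.

A cohort mixing ``g`` latent groups over ``s`` stages lives in an ``s*g``
vector ``n``.  The canonical ordering here is **group-major**: stages are
contiguous within each group, entry ``k*s + i`` holding stage ``i`` of group
``k``.  The projection matrix is

    U_tilde = K.T @ D @ K @ scriptU

where ``scriptU = blockdiag(U_1 .. U_g)`` moves individuals among stages
within their group (acting on the group-major vector), ``K`` is the
vec-permutation (commutation) matrix converting group-major to **stage-major**
ordering (entry ``i*g + k``), and ``D = blockdiag(D_1 .. D_s)`` moves
individuals among groups within each stage.  With fixed heterogeneity every
``D_i`` is the identity and ``U_tilde`` reduces to ``scriptU``.

Projection is pure attrition — no reproduction feeds back into the cohort —
so total abundance is non-increasing and the group composition among
survivors traces intra-cohort selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .model import STAGES, MixtureModel, stage_index

__all__ = [
    "vec_permutation_matrix",
    "BlockProjection",
    "build_block_projection",
    "initial_cohort",
    "CohortTrajectory",
    "project_cohort",
    "cohort_composition",
]


def vec_permutation_matrix(s: int, g: int) -> np.ndarray:
    """Vec-permutation matrix mapping group-major to stage-major ordering.

    ``K[i*g + k, k*s + i] = 1`` for stage ``i``, group ``k``; equivalently the
    commutation matrix with ``K vec(X) = vec(X.T)`` for an ``s x g`` matrix
    ``X`` whose columns are groups.
    """
    if s < 1 or g < 1:
        raise ValueError("s and g must be positive")
    K = np.zeros((s * g, s * g))
    for i in range(s):
        for k in range(g):
            K[i * g + k, k * s + i] = 1.0
    return K


@dataclass(frozen=True)
class BlockProjection:
    """Assembled block projection: ``Utilde = K.T @ scriptD @ K @ scriptU``."""

    Utilde: np.ndarray
    K: np.ndarray
    scriptU: np.ndarray
    scriptD: np.ndarray
    s: int
    g: int
    labels: tuple[str, ...]


def build_block_projection(mixture: MixtureModel,
                           D: Sequence[np.ndarray] | None = None) -> BlockProjection:
    """Assemble the ``sg x sg`` projection matrix for a heterogeneous cohort.

    ``D`` is an optional list of ``s`` column-stochastic ``g x g`` matrices of
    group transitions, one per stage; omitted (fixed heterogeneity) it
    defaults to identities, in which case ``Utilde`` equals
    ``blockdiag(U_1 .. U_g)`` exactly.
    """
    s, g = mixture.s, mixture.g
    scriptU = block_diag(*[c.U for c in mixture.chains])
    if D is None:
        Dmats = [np.eye(g) for _ in range(s)]
    else:
        Dmats = [np.asarray(d, dtype=float) for d in D]
        if len(Dmats) != s:
            raise ValueError(f"need one {g}x{g} group-transition matrix per stage ({s}), got {len(Dmats)}")
        for i, d in enumerate(Dmats):
            if d.shape != (g, g):
                raise ValueError(f"D[{i}] must be {g}x{g}, got {d.shape}")
            if np.any(d < 0) or np.any(np.abs(d.sum(axis=0) - 1.0) > 1e-12):
                raise ValueError(f"D[{i}] must be column-stochastic")
    scriptD = block_diag(*Dmats)
    K = vec_permutation_matrix(s, g)
    Utilde = K.T @ scriptD @ K @ scriptU
    return BlockProjection(Utilde=Utilde, K=K, scriptU=scriptU, scriptD=scriptD,
                           s=s, g=g, labels=mixture.labels)


def initial_cohort(mixture: MixtureModel, stage: int | str = "PB",
                   total: float = 1.0) -> np.ndarray:
    """Group-major cohort vector with all individuals in one stage, split by ``pi``."""
    n0 = np.zeros(mixture.s * mixture.g)
    i = stage_index(stage)
    for k in range(mixture.g):
        n0[k * mixture.s + i] = total * mixture.pi[k]
    return n0


@dataclass(frozen=True)
class CohortTrajectory:
    """Time-indexed stage-by-group abundances, ``data[t]`` group-major at time ``t``."""

    data: np.ndarray  # (horizon + 1, s*g)
    s: int
    g: int
    labels: tuple[str, ...]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[0])

    def abundance(self, t: int) -> np.ndarray:
        """Abundance at time ``t`` reshaped to (group, stage)."""
        return self.data[t].reshape(self.g, self.s)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (t, group, stage)."""
        records = []
        for t in self.times:
            block = self.abundance(t)
            for k, lab in enumerate(self.labels):
                for i, st in enumerate(STAGES):
                    records.append((int(t), lab, st, block[k, i]))
        return pd.DataFrame(records, columns=["t", "group", "stage", "abundance"])


def project_cohort(bp: BlockProjection, n0: np.ndarray, horizon: int = 100) -> CohortTrajectory:
    """Project ``n(t+1) = Utilde n(t)`` and keep every step ``t = 0..horizon``."""
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (bp.s * bp.g,):
        raise ValueError(f"n0 must have length {bp.s * bp.g}, got {n0.shape}")
    if np.any(n0 < 0):
        raise ValueError("n0 must be non-negative")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    out = np.empty((horizon + 1, n0.size))
    out[0] = n0
    for t in range(horizon):
        out[t + 1] = bp.Utilde @ out[t]
    return CohortTrajectory(data=out, s=bp.s, g=bp.g, labels=bp.labels)


def cohort_composition(traj: CohortTrajectory) -> pd.DataFrame:
    """Per-time survivorship and group composition among survivors.

    Columns: ``t``, ``survivorship`` (total alive / initial total), ``defined``
    (False once the cohort is extinct to machine precision; shares are NaN
    there and flagged, so downstream code can filter explicitly), plus
    ``share_<group>`` (fraction of survivors) and ``initial_share_<group>``
    (fraction of the initial cohort still alive in that group).
    """
    total0 = traj.data[0].sum()
    if total0 <= 0:
        raise ValueError("initial cohort is empty")
    rows = []
    for t in traj.times:
        block = traj.abundance(t)
        by_group = block.sum(axis=1)
        alive = by_group.sum()
        defined = alive > 0
        row = {"t": int(t), "survivorship": alive / total0, "defined": defined}
        for k, lab in enumerate(traj.labels):
            row[f"share_{lab}"] = by_group[k] / alive if defined else np.nan
            row[f"initial_share_{lab}"] = by_group[k] / total0
        rows.append(row)
    return pd.DataFrame(rows)
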