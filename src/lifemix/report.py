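"""Assembly of the full analysis report from a fitted mixture model.

Every number in the report is recomputed from the input parameter file alone;
the provenance block records the SHA-256 of the inputs, the package version
and any seed so reports are reproducible and diffable.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import STAGES, MixtureModel
from .outcomes import (
    FirstPassageSpec,
    breeding_interval,
    expected_lro,
    first_passage,
    fundamental_matrix,
    longevity_moments,
    occupancy_proportions,
    occupancy_variance,
    recruitment_start,
)
from .decompose import decompose_outcome, mixture_mean

__all__ = ["build_report", "report_to_csvs", "file_checksum"]

_ADULTS = ("S", "F", "NB")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _matrix_dict(A: np.ndarray) -> dict:
    return {to: {frm: float(A[i, j]) for j, frm in enumerate(STAGES)}
            for i, to in enumerate(STAGES)}


def group_outcome_table(mixture: MixtureModel) -> pd.DataFrame:
    """Per-group first-passage summary mirroring the published layout.

    Rows: mean age at first recruitment, probability of recruiting before
    death, mean age at first successful reproduction, probability of breeding
    successfully before death, and the conditional interval to the next
    successful breeding from each adult stage.
    """
    rows = {}
    recruit = {}
    success = {}
    for chain in mixture.chains:
        recruit[chain.label] = first_passage(chain.U, chain.M, FirstPassageSpec(target=("S", "F")), chain.label)
        success[chain.label] = first_passage(chain.U, chain.M, FirstPassageSpec(target=("S",)), chain.label)
    labels = mixture.labels
    rows["mean_age_first_recruitment"] = [recruit[l].for_stage("PB")[0] for l in labels]
    rows["prob_recruit_before_death"] = [recruit[l].for_stage("PB")[2] for l in labels]
    rows["mean_age_first_success"] = [success[l].for_stage("PB")[0] for l in labels]
    rows["prob_success_before_death"] = [success[l].for_stage("PB")[2] for l in labels]
    for st in _ADULTS:
        rows[f"breeding_interval_from_{st}"] = [
            breeding_interval(c.U, c.M, st, label=c.label)[0] for c in mixture.chains
        ]
    return pd.DataFrame(rows, index=list(labels)).T.rename_axis("quantity")


def decomposition_table(mixture: MixtureModel) -> pd.DataFrame:
    """Variance components (within, between, percent) per outcome."""
    cols = {}
    for outcome in ("longevity", "lro", "age_first_reproduction"):
        d = decompose_outcome(mixture, outcome)
        cols[outcome] = {"within": d.within, "between": d.between,
                         "total": d.total, "pct_heterogeneity": d.pct_heterogeneity}
    return pd.DataFrame(cols).rename_axis("component")


def build_report(mixture: MixtureModel, *, inputs: dict[str, str] | None = None,
                 seed: int | None = None) -> dict:
    """Full analysis report as a JSON-serializable dict."""
    groups = {}
    for chain in mixture.chains:
        N = fundamental_matrix(chain.U, chain.label)
        V = occupancy_variance(N)
        lon = longevity_moments(chain.U, chain.label)
        lro = expected_lro(chain.U, chain.label)
        groups[chain.label] = {
            "vital_rates": {
                "survival": chain.rates.sigma.tolist() if chain.rates is not None else None,
                "breeding": chain.rates.beta.tolist() if chain.rates is not None else None,
                "success": chain.rates.gamma.tolist() if chain.rates is not None else None,
            },
            "fundamental_matrix": _matrix_dict(N),
            "occupancy_variance": _matrix_dict(V),
            "longevity_mean": dict(zip(STAGES, lon.mean.tolist())),
            "longevity_variance": dict(zip(STAGES, lon.variance.tolist())),
            "lro_mean": dict(zip(STAGES, lro.mean.tolist())),
            "lro_variance": dict(zip(STAGES, lro.variance.tolist())),
            "occupancy_share_whole_life": dict(
                zip(STAGES, occupancy_proportions(chain.U, "PB", chain.label).tolist())
            ),
            "occupancy_share_adult_life": dict(
                zip(STAGES, occupancy_proportions(chain.U, recruitment_start(chain), chain.label).tolist())
            ),
        }
    outcome_table = group_outcome_table(mixture)
    decomp_table = decomposition_table(mixture)
    report = {
        "stages": list(STAGES),
        "mixing_distribution": dict(zip(mixture.labels, mixture.pi.tolist())),
        "groups": groups,
        "first_passage_table": {q: dict(zip(outcome_table.columns, row))
                                for q, row in outcome_table.iterrows()},
        "variance_decomposition": {outcome: decomp_table[outcome].to_dict()
                                   for outcome in decomp_table.columns},
        "mixture_summaries": {
            "mean_longevity": mixture_mean(mixture, "longevity"),
            "mean_lro": mixture_mean(mixture, "lro"),
            "mean_age_first_reproduction": mixture_mean(mixture, "age_first_reproduction"),
        },
        "provenance": {
            "package": "lifemix",
            "version": __version__,
            "inputs": inputs or {},
            "seed": seed,
        },
    }
    return report


def report_to_csvs(report: dict, out_dir: str | Path) -> list[Path]:
    """Write the tabular blocks of a report as CSV files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for label, blk in report["groups"].items():
        for key in ("fundamental_matrix", "occupancy_variance"):
            df = pd.DataFrame(blk[key]).T  # rows = to-stage, cols = from-stage
            df = df.loc[list(STAGES), list(STAGES)].rename_axis("stage")
            path = out / f"{key}_{label}.csv"
            df.to_csv(path, float_format="%.10g")
            written.append(path)

    occ_rows = []
    for label, blk in report["groups"].items():
        for scopekey, scope in (("occupancy_share_whole_life", "whole_life"),
                                ("occupancy_share_adult_life", "adult_life")):
            for st, share in blk[scopekey].items():
                occ_rows.append({"group": label, "scope": scope, "stage": st, "share": share})
    path = out / "occupancy_shares.csv"
    pd.DataFrame(occ_rows).to_csv(path, index=False, float_format="%.10g")
    written.append(path)

    fp = pd.DataFrame(report["first_passage_table"]).T.rename_axis("quantity")
    path = out / "first_passage_table.csv"
    fp.to_csv(path, float_format="%.10g")
    written.append(path)

    vd = pd.DataFrame(report["variance_decomposition"]).rename_axis("component")
    path = out / "variance_decomposition.csv"
    vd.to_csv(path, float_format="%.10g")
    written.append(path)

    return written
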