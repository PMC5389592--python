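"""Mass-based peptide annotation and protein-level aggregation.

Clusters are matched against a candidate sequence table (ground truth in the
synthetic pipeline, or user-supplied identifications) by smallest absolute
ppm error within a tolerance that defaults to the clustering mass tolerance
at the cluster's mass.  Protein-level abundance is the per-sample sum of the
protein's annotated peptide rows — the statistic behind the summed
uromodulin-fragment signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import compute_peptide_mass
from .clustering import PeptideCluster, ToleranceConfig, mass_tolerance
from .stats import StatsConfig, fold_change, group_columns

__all__ = [
    "compute_peptide_mass",
    "candidate_table_from_ground_truth",
    "annotate_clusters",
    "summarize_protein",
    "ProteinSummary",
]


def candidate_table_from_ground_truth(ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Candidate sequences (sequence, parent, coordinates, mass) for lookup."""
    cols = ["sequence", "parent_protein", "start_pos", "end_pos"]
    table = ground_truth[cols].copy()
    if "true_mass" in ground_truth:
        table["mass"] = ground_truth["true_mass"]
    else:
        table["mass"] = table["sequence"].map(compute_peptide_mass)
    return table


def annotate_clusters(
    clusters: list[PeptideCluster] | pd.DataFrame,
    candidates: pd.DataFrame,
    ppm_tolerance: float | None = None,
    cfg: ToleranceConfig | None = None,
) -> pd.DataFrame:
    """One-to-one nearest-mass assignment of candidates to clusters.

    All (cluster, candidate) pairs within tolerance are ranked by |ppm error|
    and assigned greedily, so each cluster gets the closest available
    candidate and each candidate annotates at most one cluster.  Clusters
    with no candidate in tolerance are left out of the result.

    ``clusters`` may be the cluster list or a summary frame with
    ``peptide_id`` and ``centroid_mass`` columns.  ``ppm_tolerance`` fixes
    one window for all clusters; by default the clustering mass-tolerance
    ramp at each cluster's mass is used.
    """
    if isinstance(clusters, pd.DataFrame):
        ids = clusters["peptide_id"].to_numpy()
        masses = clusters["centroid_mass"].to_numpy(dtype=float)
    else:
        ids = np.array([c.peptide_id for c in clusters])
        masses = np.array([c.centroid_mass for c in clusters])
    if len(ids) == 0 or candidates.empty:
        return pd.DataFrame(
            columns=["peptide_id", "sequence", "parent_protein",
                     "start_pos", "end_pos", "ppm_error"]
        )
    cand_mass = candidates["mass"].to_numpy(dtype=float)
    tol = (
        np.full(len(ids), float(ppm_tolerance))
        if ppm_tolerance is not None
        else mass_tolerance(masses, cfg or ToleranceConfig())
    )
    ppm = (masses[:, None] - cand_mass[None, :]) / cand_mass[None, :] * 1e6
    within = np.abs(ppm) <= np.atleast_1d(tol)[:, None]
    ci, cj = np.nonzero(within)
    order = np.argsort(np.abs(ppm[ci, cj]), kind="mergesort")
    used_cluster: set[int] = set()
    used_cand: set[int] = set()
    rows = []
    for k in order:
        i, j = int(ci[k]), int(cj[k])
        if i in used_cluster or j in used_cand:
            continue
        used_cluster.add(i)
        used_cand.add(j)
        cand = candidates.iloc[j]
        rows.append(
            {
                "peptide_id": ids[i],
                "sequence": cand.sequence,
                "parent_protein": cand.parent_protein,
                "start_pos": int(cand.start_pos),
                "end_pos": int(cand.end_pos),
                "ppm_error": float(ppm[i, j]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["peptide_id", "sequence", "parent_protein",
                 "start_pos", "end_pos", "ppm_error"],
    )
    return out.sort_values("peptide_id").reset_index(drop=True)


@dataclass
class ProteinSummary:
    """Summed peptide-level signal for one parent protein."""

    protein: str
    peptide_ids: list[int]
    per_sample: pd.Series  # summed intensity per sample
    group_means: pd.DataFrame  # strain × time_point means of the sum
    fold_changes: pd.DataFrame  # per time point, hypertensive/control


def summarize_protein(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    protein: str,
    design: pd.DataFrame,
    hypertensive: str | None = None,
    cfg: StatsConfig | None = None,
) -> ProteinSummary:
    """Per-sample summed intensity over one protein's annotated peptides,
    with group means and between-strain fold changes per time point."""
    pep_ids = annotations.loc[
        annotations.parent_protein == protein, "peptide_id"
    ].tolist()
    if not pep_ids:
        raise ValueError(f"no annotated peptides for protein {protein!r}")
    per_sample = matrix.loc[pep_ids].sum(axis=0)

    strains = list(dict.fromkeys(design["strain"]))
    time_points = list(dict.fromkeys(design["time_point"]))
    if hypertensive is None:
        hypertensive = strains[-1]
    control = next(s for s in strains if s != hypertensive)
    groups = group_columns(design)

    means = pd.DataFrame(index=strains, columns=time_points, dtype=float)
    for (strain, tp), cols in groups.items():
        means.loc[strain, tp] = float(per_sample[cols].mean())

    fc_rows = []
    for tp in time_points:
        a = per_sample[groups[(hypertensive, tp)]].to_numpy()
        b = per_sample[groups[(control, tp)]].to_numpy()
        fc, flag = fold_change(a, b)
        fc_rows.append({"time_point": tp, "fold_change": fc, "fc_flag": flag})
    return ProteinSummary(
        protein=protein,
        peptide_ids=pep_ids,
        per_sample=per_sample,
        group_means=means,
        fold_changes=pd.DataFrame(fc_rows),
    )
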