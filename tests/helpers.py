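"""Shared test utilities: pipeline shortcuts and independent brute-force
oracles (kept free of the implementation paths they check)."""

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from pepticlust import calibration, clustering
from pepticlust.clustering import ToleranceConfig, mass_tolerance, time_tolerance


def run_through_matrix(study):
    """Calibrate and cluster a study; return (matrix, cluster summary)."""
    calibrated, _ = calibration.calibrate_study(
        study.peak_lists, study.calibrant_reference
    )
    clusters = clustering.cluster_peaks(calibrated)
    return clustering.build_matrix(clusters, study.design)


def brute_force_rank_sum(a, b):
    """Two-sided rank-sum p by complete enumeration, with its own mid-ranking."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank of 1-based positions
        i = j
    n_a = len(a)
    expect = n_a * ranks.mean()
    obs = abs(ranks[:n_a].sum() - expect)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - expect) >= obs - 1e-9:
            count += 1
    return count / total


def make_separated_instance(rng, n_clusters=25, n_samples=8, max_members=5):
    """Random peaks whose compatibility components sit far beyond 2x tolerance
    (4000 ppm mass spacing between components)."""
    cfg = ToleranceConfig()
    rows = []
    base_masses = 900.0 * (1.004 ** np.arange(n_clusters))
    times = rng.uniform(20, 48, n_clusters)
    for k in range(n_clusters):
        size = int(rng.integers(1, min(max_members, n_samples) + 1))
        samples = rng.choice(n_samples, size=size, replace=False)
        mtol = base_masses[k] * mass_tolerance(base_masses[k], cfg) * 1e-6
        ttol = time_tolerance(times[k], cfg)
        for s in samples:
            rows.append(
                (
                    f"S{s:02d}",
                    base_masses[k] + rng.uniform(-0.3, 0.3) * mtol,
                    times[k] + rng.uniform(-0.3, 0.3) * ttol,
                    float(rng.uniform(1, 100)),
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "mass_da", "time_min", "intensity"])


def single_linkage_oracle(df, cfg=None):
    """Connected components of the pairwise tolerance-compatibility graph."""
    cfg = cfg or ToleranceConfig()
    m = df.mass_da.to_numpy()
    t = df.time_min.to_numpy()
    mid_mass = (m[:, None] + m[None, :]) / 2
    mtol = mid_mass * mass_tolerance(mid_mass.ravel(), cfg).reshape(mid_mass.shape) * 1e-6
    ttol = time_tolerance(
        np.maximum((t[:, None] + t[None, :]) / 2, 1e-9).ravel(), cfg
    ).reshape(mid_mass.shape)
    compatible = (np.abs(m[:, None] - m[None, :]) <= mtol) & (
        np.abs(t[:, None] - t[None, :]) <= ttol
    )
    _, labels = connected_components(csr_matrix(compatible), directed=False)
    return labels


def oracle_partition(labels, df):
    groups = {}
    for lab, (_, row) in zip(labels, df.iterrows()):
        groups.setdefault(lab, set()).add(
            (row.sample_id, round(float(row.mass_da), 9), round(float(row.time_min), 9))
        )
    return {frozenset(g) for g in groups.values()}


def greedy_partition(df, cfg=None):
    lists = {
        s: sub[["mass_da", "time_min", "intensity"]].reset_index(drop=True)
        for s, sub in df.groupby("sample_id")
    }
    clusters = clustering.cluster_peaks(lists, cfg)
    return {
        frozenset(
            (s, round(float(m), 9), round(float(t), 9))
            for s, (_, m, t) in c.members.items()
        )
        for c in clusters
    }
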