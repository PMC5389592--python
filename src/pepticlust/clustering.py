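"""Cross-sample peptide clustering with variable tolerance windows.

Peaks from calibrated samples are matched into consensus peptides under two
criteria, both of which must hold: a mass window of ±50 ppm below 800 Da
widening linearly to ±75 ppm at 20 kDa, and a migration-time window widening
linearly from ±0.4 min at 19 min to ±2.5 min at 50 min (clamped outside both
ranges).  Clusters are built by a deterministic greedy running-centroid pass
— the incremental equivalent of annotating each new sample against a growing
consensus database — with at most one peak per sample per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ToleranceConfig:
    """Anchors of the mass (ppm) and migration-time (min) tolerance ramps."""

    ppm_small: float = 50.0
    ppm_large: float = 75.0
    mass_low: float = 800.0
    mass_high: float = 20000.0
    time_tol_low: float = 0.4
    time_tol_high: float = 2.5
    time_low: float = 19.0
    time_high: float = 50.0

    def __post_init__(self) -> None:
        if not (self.ppm_small <= self.ppm_large and self.time_tol_low <= self.time_tol_high):
            raise ValueError("tolerance ramps must be non-decreasing")
        if not (self.mass_low < self.mass_high and self.time_low < self.time_high):
            raise ValueError("ramp anchor ranges must be non-degenerate")


def mass_tolerance(mass, cfg: ToleranceConfig | None = None):
    """Mass-matching half-window in ppm at the given mass (Da)."""
    cfg = cfg or ToleranceConfig()
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    frac = np.clip((m - cfg.mass_low) / (cfg.mass_high - cfg.mass_low), 0.0, 1.0)
    out = cfg.ppm_small + (cfg.ppm_large - cfg.ppm_small) * frac
    return float(out) if np.isscalar(mass) else out


def time_tolerance(time, cfg: ToleranceConfig | None = None):
    """Migration-time matching half-window in minutes at the given time."""
    cfg = cfg or ToleranceConfig()
    t = np.asarray(time, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be positive")
    frac = np.clip((t - cfg.time_low) / (cfg.time_high - cfg.time_low), 0.0, 1.0)
    out = cfg.time_tol_low + (cfg.time_tol_high - cfg.time_tol_low) * frac
    return float(out) if np.isscalar(time) else out


@dataclass
class PeptideCluster:
    """A consensus peptide: centroid plus at most one member peak per sample."""

    peptide_id: int
    centroid_mass: float
    centroid_time: float
    members: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # sample_id -> (intensity, observed mass, observed time)

    @property
    def n_samples(self) -> int:
        return len(self.members)


def cluster_peaks(
    peak_lists: dict[str, pd.DataFrame],
    cfg: ToleranceConfig | None = None,
) -> list[PeptideCluster]:
    """Greedy running-centroid clustering over all samples.

    Samples are processed in sorted sample_id order.  Within a sample, peaks
    are matched nearest-first: each peak's admissible centroids are those
    within both tolerance windows (Chebyshev distance in tolerance-normalized
    units ≤ 1) whose cluster holds no peak from this sample yet; the peak
    joins the nearest admissible centroid (normalized Euclidean tie-break is
    implicit in the nearest-first ordering) and the centroid is updated to
    the running mean of its members.  Unmatched peaks seed new clusters.
    Nearest-first processing makes the one-peak-per-sample conflict rule
    "closer peak wins" hold without explicit displacement.
    """
    cfg = cfg or ToleranceConfig()
    # growable centroid arrays
    cap = 1024
    c_mass = np.empty(cap)
    c_time = np.empty(cap)
    c_count = np.empty(cap, dtype=np.int64)
    n_clusters = 0
    clusters: list[PeptideCluster] = []

    for sample_id in sorted(peak_lists):
        df = peak_lists[sample_id]
        masses = df["mass_da"].to_numpy(dtype=float)
        times = df["time_min"].to_numpy(dtype=float)
        intensities = df["intensity"].to_numpy(dtype=float)
        # which pre-existing clusters already hold a peak from this sample;
        # clusters seeded during this sample never take a second same-sample
        # peak either, and peaks only match centroids existing at sample start
        taken = np.zeros(n_clusters, dtype=bool)

        if n_clusters == 0:
            order = np.argsort(masses, kind="mergesort")
            dists = None
        else:
            cm = c_mass[:n_clusters]
            ct = c_time[:n_clusters]
            m_tol = cm * mass_tolerance(cm, cfg) * 1e-6
            t_tol = time_tolerance(np.maximum(ct, 1e-9), cfg)
            # peak x cluster normalized Chebyshev distances
            dm = np.abs(masses[:, None] - cm[None, :]) / m_tol[None, :]
            dt = np.abs(times[:, None] - ct[None, :]) / t_tol[None, :]
            dists = np.maximum(dm, dt)
            eucl = np.hypot(dm, dt)  # tie-break metric
            nearest = dists.min(axis=1, initial=np.inf)
            order = np.argsort(nearest, kind="mergesort")

        for i in order:
            assigned = -1
            if dists is not None:
                row = dists[i].copy()
                row[taken] = np.inf
                j = int(np.argmin(row))
                tied = np.flatnonzero(row <= row[j] + 1e-12)
                if tied.size > 1:  # Chebyshev tie: break by normalized Euclidean
                    j = int(tied[np.argmin(eucl[i, tied])])
                if row[j] <= 1.0:
                    # re-verify against the *current* centroid (it may have
                    # moved since distances were computed at sample start)
                    if _within(masses[i], times[i], c_mass[j], c_time[j], cfg):
                        assigned = j
            if assigned >= 0:
                cl = clusters[assigned]
                cl.members[sample_id] = (intensities[i], masses[i], times[i])
                k = c_count[assigned] + 1
                c_mass[assigned] += (masses[i] - c_mass[assigned]) / k
                c_time[assigned] += (times[i] - c_time[assigned]) / k
                c_count[assigned] = k
                cl.centroid_mass = float(c_mass[assigned])
                cl.centroid_time = float(c_time[assigned])
                taken[assigned] = True
            else:
                if n_clusters == cap:
                    cap *= 2
                    c_mass = np.resize(c_mass, cap)
                    c_time = np.resize(c_time, cap)
                    c_count = np.resize(c_count, cap)
                c_mass[n_clusters] = masses[i]
                c_time[n_clusters] = times[i]
                c_count[n_clusters] = 1
                clusters.append(
                    PeptideCluster(
                        peptide_id=n_clusters,
                        centroid_mass=float(masses[i]),
                        centroid_time=float(times[i]),
                        members={sample_id: (intensities[i], masses[i], times[i])},
                    )
                )
                n_clusters += 1
    return clusters


def _within(mass, time, cmass, ctime, cfg: ToleranceConfig) -> bool:
    m_tol = cmass * mass_tolerance(cmass, cfg) * 1e-6
    t_tol = time_tolerance(max(ctime, 1e-9), cfg)
    return abs(mass - cmass) <= m_tol and abs(time - ctime) <= t_tol


def build_matrix(
    clusters: list[PeptideCluster],
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clusters × samples intensity matrix (zero = not detected).

    Rows are ordered by (centroid mass, centroid time); columns follow the
    design's sample order.  Returns the matrix and a cluster summary table
    ``peptide_id  centroid_mass  centroid_time  n_samples``.
    """
    sample_ids = list(design["sample_id"])
    sample_set = set(sample_ids)
    for cl in clusters:
        unknown = set(cl.members) - sample_set
        if unknown:
            raise ValueError(
                f"cluster {cl.peptide_id} references unknown sample id "
                f"{sorted(unknown)[0]!r}"
            )
    ordered = sorted(clusters, key=lambda c: (c.centroid_mass, c.centroid_time))
    data = np.zeros((len(ordered), len(sample_ids)))
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, cl in enumerate(ordered):
        for s, (intensity, _, _) in cl.members.items():
            data[i, col[s]] = intensity
    matrix = pd.DataFrame(
        data,
        index=pd.Index([c.peptide_id for c in ordered], name="peptide_id"),
        columns=sample_ids,
    )
    summary = pd.DataFrame(
        {
            "peptide_id": [c.peptide_id for c in ordered],
            "centroid_mass": [c.centroid_mass for c in ordered],
            "centroid_time": [c.centroid_time for c in ordered],
            "n_samples": [c.n_samples for c in ordered],
        }
    )
    return matrix, summary


def permutation_robustness(
    peak_lists: dict[str, pd.DataFrame],
    cfg: ToleranceConfig | None = None,
    n_permutations: int = 5,
    seed: int = 0,
) -> float:
    """Fraction of peaks whose cluster assignment changes under random
    sample-order permutations (diagnostic; 0 on well-separated data).

    Assignment is compared via the partition of (sample, peak-row) labels.
    """
    def partition(order: list[str]) -> set[frozenset]:
        renamed = {f"{i:06d}|{s}": peak_lists[s] for i, s in enumerate(order)}
        clusters = cluster_peaks(renamed, cfg)
        out = set()
        for cl in clusters:
            out.add(
                frozenset(
                    (s.split("|", 1)[1], round(m, 9), round(t, 9))
                    for s, (_, m, t) in cl.members.items()
                )
            )
        return out

    base_order = sorted(peak_lists)
    base = partition(base_order)
    n_peaks = sum(len(df) for df in peak_lists.values())
    if n_peaks == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    changed = 0
    for _ in range(n_permutations):
        order = list(base_order)
        rng.shuffle(order)
        perm = partition(order)
        stable = base & perm
        stable_peaks = sum(len(group) for group in stable)
        changed = max(changed, n_peaks - stable_peaks)
    return changed / n_peaks
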