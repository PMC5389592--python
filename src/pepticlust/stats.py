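"""Differential-abundance statistics for the clusters × samples matrix.

The chain mirrors a standard CE-MS biomarker screen: a detection-frequency
filter (≥70% in at least one strain × time-point group), a two-sided Wilcoxon
rank-sum test per peptide and comparison with Benjamini–Hochberg adjustment
per comparison family, repeated-measures ANOVA across gestational days as the
longitudinal confirmation, a ≥1.5-fold regulation call, and classification of
each peptide's significance pattern across time points (significant at all
time points, or at GD12 and GD18 only, are the patterns retained for further
analysis).

Non-detections enter the tests as intensity zero (the conventional reading of
a peptide absent from a CE-MS peak list); an NA-exclusion alternative is
available via ``treat_zero_as_missing``.

The rank-sum p-value is permutation-exact — complete enumeration of the
C(nA+nB, nA) group assignments of the mid-ranks — whenever that enumeration
is small enough (it always is at the study's n = 7 per group), which handles
ties exactly; larger groups fall back to the normal approximation with tie
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_ENUMERATION_LIMIT = 200_000  # max C(n, nA) for the exact path


@dataclass
class StatsConfig:
    frequency_threshold: float = 0.70
    alpha: float = 0.05
    fold_change_cutoff: float = 1.5
    treat_zero_as_missing: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_change_cutoff < 1:
            raise ValueError("fold_change_cutoff must be >= 1")


# ---------------------------------------------------------------------------
# building blocks


def group_columns(design: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """sample ids per (strain, time_point) group, in design order."""
    out: dict[tuple[str, str], list[str]] = {}
    for _, row in design.iterrows():
        out.setdefault((row.strain, row.time_point), []).append(row.sample_id)
    return out


def frequency_filter(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    cfg: StatsConfig | None = None,
) -> pd.Index:
    """Peptides detected in ≥ threshold of samples in at least one group."""
    cfg = cfg or StatsConfig()
    groups = group_columns(design)
    if not groups:
        raise ValueError("design defines no (strain, time_point) groups")
    missing = set(design.sample_id) - set(matrix.columns)
    if missing:
        raise ValueError(f"design group samples missing from matrix: {sorted(missing)[0]!r}")
    best = np.zeros(len(matrix))
    for cols in groups.values():
        frac = (matrix[cols].to_numpy() > 0).mean(axis=1)
        best = np.maximum(best, frac)
    # >= with a float-safe epsilon so 5/7 passes a 0.70 threshold exactly
    return matrix.index[best >= cfg.frequency_threshold - 1e-12]


@lru_cache(maxsize=32)
def _membership_matrix(n: int, k: int) -> np.ndarray:
    """Boolean (C(n,k) × n) matrix of all k-subsets of range(n)."""
    rows = np.zeros((comb(n, k), n), dtype=bool)
    for r, idx in enumerate(combinations(range(n), k)):
        rows[r, list(idx)] = True
    return rows


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value for one pair of samples."""
    return float(
        rank_sum_batch(np.asarray(a, dtype=float)[None, :],
                       np.asarray(b, dtype=float)[None, :])[0]
    )


def rank_sum_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values for many peptides at once.

    ``a`` and ``b`` are (n_peptides × nA) and (n_peptides × nB) arrays.
    Exact permutation p (complete enumeration over mid-ranks, so ties are
    handled exactly): p = P(|W − E[W]| ≥ |w_obs − E[W]|) over all
    C(nA+nB, nA) assignments.  Falls back to the tie-corrected normal
    approximation when the enumeration exceeds ``EXACT_ENUMERATION_LIMIT``.
    Rows with all values identical across both groups get p = 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("a and b must have the same number of rows")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b
    pooled = np.concatenate([a, b], axis=1)
    ranks = sps.rankdata(pooled, axis=1)  # mid-ranks
    w_obs = ranks[:, :n_a].sum(axis=1)
    constant = np.ptp(pooled, axis=1) == 0

    if comb(n, n_a) <= EXACT_ENUMERATION_LIMIT:
        member = _membership_matrix(n, n_a)
        sums = ranks @ member.T  # (n_peptides × n_comb)
        expect = n_a * ranks.mean(axis=1)
        obs_dev = np.abs(w_obs - expect)
        p = (np.abs(sums - expect[:, None]) >= obs_dev[:, None] - 1e-9).mean(axis=1)
    else:
        mu = n_a * (n + 1) / 2.0
        # tie correction from the pooled rank multiplicities
        p = np.empty(a.shape[0])
        for i in range(a.shape[0]):
            _, counts = np.unique(pooled[i], return_counts=True)
            tie_term = (counts**3 - counts).sum() / ((n) * (n - 1))
            var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
            if var <= 0:
                p[i] = 1.0
                continue
            z = (abs(w_obs[i] - mu) - 0.5) / np.sqrt(var)
            p[i] = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    p = np.where(constant, 1.0, p)
    return np.minimum(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rm_anova(values: np.ndarray) -> float:
    """One-way within-subject ANOVA p-value.

    ``values`` is (subjects × time points), complete cases only.
    F = MS_time / MS_(time × subject) on (t−1) and (t−1)(s−1) df.
    Returns 1.0 when there is no time effect (SS_time = 0) and 0.0 in the
    degenerate perfectly-consistent case (SS_error = 0 with SS_time > 0).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 time points of complete data")
    if np.isnan(x).any():
        raise ValueError("complete cases only: drop subjects with missing time points")
    s, t = x.shape
    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    time = x.mean(axis=0, keepdims=True)
    ss_time = s * float(((time - grand) ** 2).sum())
    ss_err = float(((x - subj - time + grand) ** 2).sum())
    df_time = t - 1
    df_err = (t - 1) * (s - 1)
    if ss_time <= 1e-12 * max(1.0, abs(grand)) ** 2:
        return 1.0
    if ss_err <= 0:
        return 0.0
    f = (ss_time / df_time) / (ss_err / df_err)
    return float(sps.f.sf(f, df_time, df_err))


FC_EXCLUSIVE = float("inf")


def fold_change(a, b) -> tuple[float, str]:
    """mean(A)/mean(B) with zeros included, plus a qualitative flag.

    Returns ``(ratio, flag)`` where flag is ``"ratio"``, ``"exclusive_a"``
    (B all zero, A not) or ``"undefined"`` (both groups all zero, ratio NaN).
    """
    mean_a = float(np.mean(a))
    mean_b = float(np.mean(b))
    if mean_b == 0 and mean_a == 0:
        return float("nan"), "undefined"
    if mean_b == 0:
        return FC_EXCLUSIVE, "exclusive_a"
    return mean_a / mean_b, "ratio"


def call_direction(fc: float, q: float, cfg: StatsConfig) -> str:
    """Regulation call: ≥cutoff-fold and q ≤ alpha, in either orientation."""
    if not np.isfinite(q) or q > cfg.alpha or not fc == fc:  # NaN fc
        return "none"
    if fc >= cfg.fold_change_cutoff:
        return "up"
    if fc <= 1.0 / cfg.fold_change_cutoff:
        return "down"
    return "none"


def classify_pattern(sig_np: bool, sig_gd12: bool, sig_gd18: bool) -> tuple[str, bool]:
    """Significance pattern across (NP, GD12, GD18) and retention marker."""
    flags = (bool(sig_np), bool(sig_gd12), bool(sig_gd18))
    if all(flags):
        return "all_timepoints", True
    if flags == (False, True, True):
        return "GD12_and_GD18", True
    if sum(flags) == 1:
        return "single_timepoint", False
    return "none", False


# ---------------------------------------------------------------------------
# study-level driver


@dataclass
class DifferentialResults:
    """Per-comparison tables plus the cross-time-point pattern table."""

    per_comparison: dict[str, pd.DataFrame]
    patterns: pd.DataFrame
    retained_ids: pd.Index
    config: StatsConfig = field(default_factory=StatsConfig)


def _values(matrix: pd.DataFrame, cols: list[str], missing: bool) -> np.ndarray:
    v = matrix[cols].to_numpy(dtype=float)
    if missing:
        v = np.where(v > 0, v, np.nan)
    return v


def run_differential(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    cfg: StatsConfig | None = None,
    hypertensive: str | None = None,
    time_points: tuple[str, ...] | None = None,
) -> DifferentialResults:
    """The full statistical chain on one intensity matrix.

    Cross-sectional comparisons (hypertensive vs control at each time point)
    form one BH family each; q-values drive the per-time-point significance
    flags, the pattern classification, and the regulation calls.  Fold
    changes are oriented hypertensive/control.  The repeated-measures ANOVA
    across time points is computed per strain on animals with complete
    longitudinal series.
    """
    cfg = cfg or StatsConfig()
    strains = list(dict.fromkeys(design["strain"]))
    if len(strains) != 2:
        raise ValueError(f"expected exactly 2 strains, found {strains}")
    if hypertensive is None:
        hypertensive = strains[-1]
    control = next(s for s in strains if s != hypertensive)
    if time_points is None:
        time_points = tuple(dict.fromkeys(design["time_point"]))

    retained = frequency_filter(matrix, design, cfg)
    sub = matrix.loc[retained]
    groups = group_columns(design)

    per_comparison: dict[str, pd.DataFrame] = {}
    flags = {}
    for tp in time_points:
        cols_h = groups[(hypertensive, tp)]
        cols_c = groups[(control, tp)]
        a = sub[cols_h].to_numpy(dtype=float)
        b = sub[cols_c].to_numpy(dtype=float)
        if cfg.treat_zero_as_missing:
            p = np.array(
                [
                    wilcoxon_rank_sum(row_a[row_a > 0], row_b[row_b > 0])
                    if (row_a > 0).any() and (row_b > 0).any()
                    else 1.0
                    for row_a, row_b in zip(a, b)
                ]
            )
        else:
            p = rank_sum_batch(a, b)
        q = bh_adjust(p)
        fcs, fc_flags = zip(*(fold_change(ra, rb) for ra, rb in zip(a, b))) if len(sub) else ((), ())
        table = pd.DataFrame(
            {
                "peptide_id": sub.index,
                "comparison": f"{hypertensive}_vs_{control}_{tp}",
                "p_value": p,
                "q_value": q,
                "fold_change": fcs,
                "fc_flag": fc_flags,
            }
        )
        table["direction"] = [
            call_direction(fc, qq, cfg) for fc, qq in zip(table.fold_change, table.q_value)
        ]
        per_comparison[tp] = table
        flags[tp] = q <= cfg.alpha

    # repeated-measures ANOVA per strain (complete longitudinal series only)
    rm_p = {}
    for strain in (control, hypertensive):
        sub_design = design[design.strain == strain]
        pivot = sub_design.pivot(index="animal_id", columns="time_point", values="sample_id")
        pivot = pivot.dropna()[list(time_points)]
        if len(pivot) < 2 or len(time_points) < 2:
            rm_p[strain] = np.full(len(sub), np.nan)
            continue
        cols = pivot.to_numpy().ravel()
        cube = sub[list(cols)].to_numpy(dtype=float).reshape(len(sub), len(pivot), len(time_points))
        rm_p[strain] = np.array([rm_anova(x) for x in cube])

    pattern_rows = []
    for i, pid in enumerate(sub.index):
        sig = {tp: bool(flags[tp][i]) for tp in time_points}
        pattern, keep = classify_pattern(*(sig[tp] for tp in time_points))
        pattern_rows.append(
            {
                "peptide_id": pid,
                **{f"significant_{tp}": sig[tp] for tp in time_points},
                "pattern": pattern,
                "retained_for_analysis": keep,
                "rm_anova_p": rm_p[hypertensive][i],
                f"rm_anova_p_{control}": rm_p[control][i],
                "fold_change_GD18"
                if "GD18" in time_points
                else "fold_change_last": per_comparison[time_points[-1]].fold_change.iloc[i],
            }
        )
    patterns = pd.DataFrame(
        pattern_rows,
        columns=(
            ["peptide_id"]
            + [f"significant_{tp}" for tp in time_points]
            + ["pattern", "retained_for_analysis", "rm_anova_p", f"rm_anova_p_{control}"]
            + (["fold_change_GD18"] if "GD18" in time_points else ["fold_change_last"])
        ),
    )
    return DifferentialResults(
        per_comparison=per_comparison,
        patterns=patterns,
        retained_ids=retained,
        config=cfg,
    )


def summarize_regulation(results: DifferentialResults) -> pd.DataFrame:
    """Pattern × direction contingency counts over the tested peptides.

    A peptide's direction is taken from the last time point at which it is
    significantly regulated (q ≤ alpha and beyond the fold cutoff); peptides
    with direction "none" everywhere count under direction "none".
    """
    cfg = results.config
    tps = [c.removeprefix("significant_") for c in results.patterns.columns
           if c.startswith("significant_")]
    rows = []
    for _, prow in results.patterns.iterrows():
        direction = "none"
        for tp in tps:
            table = results.per_comparison[tp]
            entry = table[table.peptide_id == prow.peptide_id].iloc[0]
            d = call_direction(entry.fold_change, entry.q_value, cfg)
            if d != "none":
                direction = d
        rows.append({"pattern": prow["pattern"], "direction": direction})
    if not rows:
        return pd.DataFrame(columns=["pattern", "direction", "count"])
    out = (
        pd.DataFrame(rows)
        .value_counts(["pattern", "direction"])
        .rename("count")
        .reset_index()
        .sort_values(["pattern", "direction"])
        .reset_index(drop=True)
    )
    return out
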