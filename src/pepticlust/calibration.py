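"""Calibrant-based per-sample normalization.

Each sample's migration times, masses, and intensities are normalized against
internal standard peptides before cross-sample clustering:

* time  — least-squares affine map from observed to reference minutes
          (global linear; an optional piecewise-linear "local" mode
          interpolates between consecutive calibrants);
* mass  — a single ppm offset (median signed deviation; TOF mass error is
          multiplicative, and the median resists one mismatched calibrant);
* intensity — one multiplicative factor equalizing the summed calibrant
          intensity across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd



class CalibrationError(RuntimeError):
    """Calibration cannot be carried out for a sample."""


@dataclass
class CalibrationModel:
    """Per-sample affine corrections estimated from matched calibrants."""

    time_slope: float
    time_intercept: float
    mass_offset_ppm: float  # median observed deviation; correction divides by (1 + off*1e-6)
    intensity_scale: float
    n_calibrants_used: int
    residual_sd_time: float
    local_time_knots: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.time_slope <= 0:
            raise CalibrationError("time map slope must be positive")
        if self.intensity_scale <= 0:
            raise CalibrationError("intensity scale must be positive")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(1.0, 0.0, 0.0, 1.0, 0, 0.0)

    def map_time(self, time: np.ndarray) -> np.ndarray:
        time = np.asarray(time, dtype=float)
        if self.local_time_knots is not None:
            obs, ref = self.local_time_knots
            # piecewise-linear between consecutive calibrants, affine
            # extrapolation outside using the end segments
            return np.interp(time, obs, ref) + np.where(
                time < obs[0],
                (time - obs[0]) * (ref[1] - ref[0]) / (obs[1] - obs[0]),
                np.where(
                    time > obs[-1],
                    (time - obs[-1]) * (ref[-1] - ref[-2]) / (obs[-1] - obs[-2]),
                    0.0,
                ),
            )
        return self.time_slope * time + self.time_intercept

    def map_mass(self, mass: np.ndarray) -> np.ndarray:
        return np.asarray(mass, dtype=float) / (1.0 + self.mass_offset_ppm * 1e-6)

    def map_intensity(self, intensity: np.ndarray) -> np.ndarray:
        return np.asarray(intensity, dtype=float) * self.intensity_scale


def match_calibrants(
    peak_list: pd.DataFrame,
    reference: pd.DataFrame,
    ppm_window: float = 100.0,
    min_matches: int = 3,
    sample_id: str = "?",
) -> pd.DataFrame:
    """Pair observed peaks with reference calibrants by nearest mass.

    Each reference calibrant is matched to at most one observed peak within a
    wide bootstrap ppm window (calibration has not happened yet, hence wider
    than the clustering tolerance); matches whose observed times break the
    reference migration order are discarded (longest-increasing-subsequence
    filter).  Raises :class:`CalibrationError` when fewer than ``min_matches``
    calibrants survive.

    Returns a frame with one row per matched calibrant: observed and
    reference mass/time/intensity plus the signed ppm deviation.
    """
    if reference.empty:
        raise ValueError("reference calibrant set is empty")
    obs_mass = peak_list["mass_da"].to_numpy()
    order = np.argsort(obs_mass)
    rows = []
    used: set[int] = set()
    for _, cal in reference.sort_values("mass_da").iterrows():
        if obs_mass.size == 0:
            break
        idx = np.searchsorted(obs_mass[order], cal.mass_da)
        candidates = [i for i in (idx - 1, idx) if 0 <= i < obs_mass.size]
        best, best_ppm = None, None
        for i in candidates:
            j = int(order[i])
            if j in used:
                continue
            ppm = (obs_mass[j] - cal.mass_da) / cal.mass_da * 1e6
            if abs(ppm) <= ppm_window and (best is None or abs(ppm) < abs(best_ppm)):
                best, best_ppm = j, ppm
        if best is not None:
            used.add(best)
            rows.append(
                {
                    "ref_mass": cal.mass_da,
                    "ref_time": cal.time_min,
                    "ref_intensity": cal.intensity,
                    "obs_mass": obs_mass[best],
                    "obs_time": peak_list["time_min"].iloc[best],
                    "obs_intensity": peak_list["intensity"].iloc[best],
                    "ppm_deviation": best_ppm,
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "ref_mass", "ref_time", "ref_intensity",
            "obs_mass", "obs_time", "obs_intensity", "ppm_deviation",
        ],
    )
    if len(pairs) >= 2:
        keep = _lis_indices(
            pairs.sort_values("ref_time")["obs_time"].to_numpy()
        )
        pairs = pairs.sort_values("ref_time").iloc[keep].reset_index(drop=True)
    if len(pairs) < min_matches:
        raise CalibrationError(
            f"sample {sample_id}: only {len(pairs)} calibrant(s) matched "
            f"(need >= {min_matches})"
        )
    return pairs


def _lis_indices(values: np.ndarray) -> list[int]:
    """Indices of the longest strictly increasing subsequence (O(n^2))."""
    n = len(values)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = int(np.argmax(best))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def fit_calibration(pairs: pd.DataFrame, local: bool = False) -> CalibrationModel:
    """Fit the per-sample correction from matched calibrant pairs.

    Time: least squares of reference time on observed time.  Mass: median
    signed ppm deviation.  Intensity: ratio of summed reference to summed
    observed calibrant intensities.
    """
    if len(pairs) < 3:
        raise CalibrationError(f"need >= 3 calibrant pairs, got {len(pairs)}")
    obs_t = pairs["obs_time"].to_numpy(dtype=float)
    ref_t = pairs["ref_time"].to_numpy(dtype=float)
    if np.ptp(obs_t) == 0:
        raise CalibrationError("degenerate calibrant design: all observed times equal")
    slope, intercept = np.polyfit(obs_t, ref_t, 1)
    residuals = ref_t - (slope * obs_t + intercept)
    obs_sum = float(pairs["obs_intensity"].sum())
    if obs_sum <= 0:
        raise CalibrationError("observed calibrant intensities sum to zero")
    knots = None
    if local:
        order = np.argsort(obs_t)
        knots = (obs_t[order], ref_t[order])
    return CalibrationModel(
        time_slope=float(slope),
        time_intercept=float(intercept),
        mass_offset_ppm=float(np.median(pairs["ppm_deviation"])),
        intensity_scale=float(pairs["ref_intensity"].sum()) / obs_sum,
        n_calibrants_used=len(pairs),
        residual_sd_time=float(np.std(residuals)),
        local_time_knots=knots,
    )


def apply_calibration(
    peak_list: pd.DataFrame,
    model: CalibrationModel,
    reference: pd.DataFrame | None = None,
    drop_calibrants: bool = False,
    ppm_window: float = 100.0,
) -> pd.DataFrame:
    """Transform every peak's time, mass, and intensity through the model.

    With ``drop_calibrants`` the peaks matching the reference calibrants
    (post-correction, within ``ppm_window``) are removed so internal
    standards do not enter clustering as analyte peptides.
    """
    out = peak_list.copy()
    out["time_min"] = model.map_time(out["time_min"].to_numpy())
    out["mass_da"] = model.map_mass(out["mass_da"].to_numpy())
    out["intensity"] = model.map_intensity(out["intensity"].to_numpy())
    if drop_calibrants:
        if reference is None:
            raise ValueError("drop_calibrants requires the reference calibrant table")
        keep = np.ones(len(out), dtype=bool)
        mass = out["mass_da"].to_numpy()
        for ref_mass in reference["mass_da"]:
            dev = np.abs(mass - ref_mass) / ref_mass * 1e6
            hit = np.flatnonzero((dev <= ppm_window) & keep)
            if hit.size:
                keep[hit[np.argmin(dev[hit])]] = False
        out = out.loc[keep]
    return out.reset_index(drop=True)


def calibrate_sample(
    peak_list: pd.DataFrame,
    reference: pd.DataFrame,
    sample_id: str = "?",
    drop_calibrants: bool = True,
    local: bool = False,
) -> tuple[pd.DataFrame, CalibrationModel]:
    """Match, fit, and apply in one step for a single sample."""
    pairs = match_calibrants(peak_list, reference, sample_id=sample_id)
    model = fit_calibration(pairs, local=local)
    calibrated = apply_calibration(
        peak_list, model, reference=reference, drop_calibrants=drop_calibrants
    )
    return calibrated, model


def calibrate_study(
    peak_lists: dict[str, pd.DataFrame],
    reference: pd.DataFrame,
    drop_calibrants: bool = True,
    local: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Calibrate every sample; aggregate failures into one error.

    Returns the calibrated peak lists and a per-sample calibration report
    (model parameters and residual SD).
    """
    calibrated: dict[str, pd.DataFrame] = {}
    report_rows = []
    failures = []
    for sample_id in sorted(peak_lists):
        try:
            peaks, model = calibrate_sample(
                peak_lists[sample_id], reference,
                sample_id=sample_id, drop_calibrants=drop_calibrants, local=local,
            )
        except CalibrationError as exc:
            failures.append(str(exc))
            continue
        calibrated[sample_id] = peaks
        report_rows.append(
            {
                "sample_id": sample_id,
                "time_slope": model.time_slope,
                "time_intercept": model.time_intercept,
                "mass_offset_ppm": model.mass_offset_ppm,
                "intensity_scale": model.intensity_scale,
                "n_calibrants_used": model.n_calibrants_used,
                "residual_sd_time": model.residual_sd_time,
            }
        )
    if failures:
        raise CalibrationError("; ".join(failures))
    return calibrated, pd.DataFrame(report_rows)
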