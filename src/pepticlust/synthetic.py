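"""Seeded synthetic CE-MS study generator.

Emulates a two-strain rat pregnancy study — a normotensive control strain (WKY)
and a hypertensive strain (SHRSP), each sampled longitudinally at prepregnancy
(NP) and gestational days 12 and 18 — producing per-sample peak lists
(neutral monoisotopic mass, CE migration time, signal intensity) plus the
ground truth needed to test every downstream stage.

The measurement model covers the nuisances the calibration stage is built to
remove: a per-sample affine migration-time drift, ppm-scale multiplicative
mass error, a per-sample global intensity factor, log-normal intensity noise,
and intensity-dependent detection dropout (logistic in log-intensity, so
low-abundance peptides drive the downstream frequency filter).  Internal
calibrant peptides — stand-ins for the housekeeping-protein standards used in
real CE-MS processing — are always detected.

Migration times are assigned by a fixed monotone logistic map of log-mass onto
the calibrated 19–50 min window plus a per-peptide jitter; only the calibrated
range matters downstream, not the physics of electrophoretic mobility.

No raw-spectrum features (charge envelopes, isotope patterns) and no
post-translational modifications are simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .chemistry import compute_peptide_mass
from .io import PEAK_COLUMNS, make_record

Strain = str
TimePoint = str

DEFAULT_STRAINS: tuple[str, str] = ("WKY", "SHRSP")
DEFAULT_HYPERTENSIVE = "SHRSP"
DEFAULT_TIME_POINTS: tuple[str, str, str] = ("NP", "GD12", "GD18")

UMOD_NAME = "UMOD_RAT_SYN"
UMOD_LENGTH = 640
#: C-terminal 18-mer released downstream of the hepsin cleavage site (R591).
UMOD_CTERM_PEPTIDE = "SGNFIDQTRVLNLGPITR"
UMOD_CTERM_START, UMOD_CTERM_END = 592, 609

#: The seven urinary Umod fragments injected by the generator: the full
#: 592–609 18-mer plus six fixed nested sub-fragments of the same region.
UMOD_FRAGMENT_COORDS: tuple[tuple[int, int], ...] = (
    (592, 609),
    (592, 605),
    (592, 601),
    (595, 609),
    (595, 605),
    (598, 609),
    (601, 609),
)

#: Fixed internal calibrant peptides ("housekeeping" standards), spread over
#: the mass range so their migration times span the calibrated window.
CALIBRANT_SEQUENCES: tuple[str, ...] = (
    "GASPVTK",
    "LDTGASPVK",
    "AVLDETKGSPR",
    "GDSLVTPAEKAGR",
    "VLSDGTPEAKGNIFR",
    "AGDLSVTPEKGNRFHTW",
    "TPGEKASVLDNIRFHQYGM",
    "GSPAVTLDEKNIRFHQWYMCS",
    "AVGLSDTPEKNIRFHQWYMCSTG",
    "LVAGSDTPEKNIRFHQWYMCSTGDE",
)
CALIBRANT_INTENSITY = 5000.0


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TruePeptide:
    """A peptide that exists in the simulated urine, calibrants included."""

    sequence: str
    parent_protein: str
    start_pos: int  # 1-based inclusive
    end_pos: int
    true_mass: float  # Da, monoisotopic
    true_time: float  # min
    base_intensity: float
    effect_profile: dict[tuple[Strain, TimePoint], float] = field(default_factory=dict)
    is_calibrant: bool = False

    def effect(self, strain: Strain, time_point: TimePoint) -> float:
        return self.effect_profile.get((strain, time_point), 1.0)


@dataclass
class MeasurementModel:
    """Per-sample measurement distortions.

    ``time_drift`` is the concrete (slope, intercept) affine distortion of
    this sample's migration times; ``dropout`` is ``(midpoint_intensity,
    steepness)`` of a logistic detection-probability curve in log-intensity,
    or ``None`` to disable dropout.
    """

    time_drift: tuple[float, float] = (1.0, 0.0)
    mass_error_sd: float = 10.0  # ppm
    time_noise_sd: float = 0.05  # min
    intensity_cv: float = 0.25
    sample_intensity_factor: float = 1.0
    dropout: tuple[float, float] | None = (300.0, 0.4)

    def __post_init__(self) -> None:
        if self.time_drift[0] <= 0:
            raise ValueError("drift slope must be positive (migration order preserved)")
        if self.sample_intensity_factor <= 0:
            raise ValueError("sample intensity factor must be positive")

    @classmethod
    def noiseless(cls) -> "MeasurementModel":
        return cls(
            time_drift=(1.0, 0.0),
            mass_error_sd=0.0,
            time_noise_sd=0.0,
            intensity_cv=0.0,
            sample_intensity_factor=1.0,
            dropout=None,
        )

    def detection_probability(self, intensity: np.ndarray) -> np.ndarray:
        """Monotone non-decreasing detection probability."""
        if self.dropout is None:
            return np.ones_like(np.asarray(intensity, dtype=float))
        midpoint, steepness = self.dropout
        z = (np.log(np.maximum(intensity, 1e-300)) - np.log(midpoint)) / steepness
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class StudyConfig:
    """Defaults reproduce the study shape: 2 strains x 7 animals x 3 time points."""

    seed: int = 0
    n_animals: int = 7
    strains: tuple[str, str] = DEFAULT_STRAINS
    hypertensive: str = DEFAULT_HYPERTENSIVE
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_background: int = 180
    n_calibrants: int = 10
    scenario: str = "paper_like"
    background_differential_fraction: float = 0.10
    background_log2fc_sd: float = 1.0
    umod_fold_gd12: float = 4.0
    umod_fold_gd18: float = 8.0
    mass_error_sd: float = 10.0
    time_noise_sd: float = 0.05
    intensity_cv: float = 0.25
    drift_slope_sd: float = 0.02
    drift_intercept_sd: float = 0.4
    sample_intensity_sd: float = 0.3  # sd of log global sample factor
    dropout_midpoint: float = 300.0
    dropout_steepness: float = 0.4
    dropout_enabled: bool = True

    def validate(self) -> None:
        problems = []
        if self.n_animals < 1:
            problems.append("n_animals: must be >= 1")
        if self.n_background < 0:
            problems.append("n_background: must be >= 0")
        if not 1 <= self.n_calibrants <= len(CALIBRANT_SEQUENCES):
            problems.append(
                f"n_calibrants: must be in [1, {len(CALIBRANT_SEQUENCES)}]"
            )
        if self.scenario not in {"null", "paper_like", "custom"}:
            problems.append(f"scenario: unknown scenario {self.scenario!r}")
        if self.hypertensive not in self.strains:
            problems.append("hypertensive: must be one of strains")
        if not 0 <= self.background_differential_fraction <= 1:
            problems.append("background_differential_fraction: must be in [0, 1]")
        for name in ("mass_error_sd", "time_noise_sd", "intensity_cv",
                     "drift_slope_sd", "drift_intercept_sd", "sample_intensity_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name}: must be >= 0")
        if problems:
            raise ValueError("invalid study config: " + "; ".join(problems))

    @classmethod
    def noiseless(cls, scenario: str = "null", **kwargs) -> "StudyConfig":
        return cls(
            scenario=scenario,
            mass_error_sd=0.0,
            time_noise_sd=0.0,
            intensity_cv=0.0,
            drift_slope_sd=0.0,
            drift_intercept_sd=0.0,
            sample_intensity_sd=0.0,
            dropout_enabled=False,
            **kwargs,
        )


@dataclass
class SyntheticStudy:
    """Everything one simulated study produces."""

    peak_lists: dict[str, pd.DataFrame]
    design: pd.DataFrame
    ground_truth: pd.DataFrame
    peptides: list[TruePeptide]
    calibrant_reference: pd.DataFrame
    protein_db: list[SeqRecord]
    config: StudyConfig


# ---------------------------------------------------------------------------
# protein database (synthetic scaffold)

_BG_PROTEIN_LENGTHS = (610, 540, 480, 430, 390, 350, 320, 300)
# residue frequencies roughly matching vertebrate proteins
_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_RESIDUE_FREQ = np.array(
    [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6,
     1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)
_RESIDUE_FREQ = _RESIDUE_FREQ / _RESIDUE_FREQ.sum()


def default_protein_db(seed: int = 97) -> list[SeqRecord]:
    """Deterministic synthetic protein database.

    The uromodulin entry is a synthetic scaffold, not the UniProt rat
    sequence: random residues except that position 591 is the hepsin-site
    arginine, positions 592–609 carry the C-terminal peptide
    ``SGNFIDQTRVLNLGPITR``, and position 615 is the GPI-attachment serine.
    Background entries are random synthetic proteins used only as parents
    for background peptide fragments.
    """
    rng = np.random.default_rng(seed)

    def random_protein(length: int) -> str:
        return "".join(rng.choice(_RESIDUES, size=length, p=_RESIDUE_FREQ))

    umod = list(random_protein(UMOD_LENGTH))
    umod[590] = "R"  # P1 of the hepsin cleavage site (residue 591)
    umod[591:609] = list(UMOD_CTERM_PEPTIDE)
    umod[614] = "S"  # GPI anchoring site
    records = [
        make_record(UMOD_NAME, "".join(umod), "synthetic uromodulin scaffold"),
    ]
    for i, length in enumerate(_BG_PROTEIN_LENGTHS, start=1):
        records.append(
            make_record(f"BGPROT{i:02d}", random_protein(length),
                        "synthetic background protein")
        )
    return records


def _find_umod(protein_db: Sequence[SeqRecord]) -> SeqRecord:
    for rec in protein_db:
        if "UMOD" in rec.id.upper():
            if len(rec.seq) < UMOD_CTERM_END:
                raise ValueError(
                    f"uromodulin record {rec.id!r} has only {len(rec.seq)} residues; "
                    f">= {UMOD_CTERM_END} required for the C-terminal fragments"
                )
            return rec
    raise ValueError(
        "no uromodulin record found in the protein database "
        "(expected an id containing 'UMOD')"
    )


# ---------------------------------------------------------------------------
# migration-time model

TIME_LOW, TIME_HIGH = 19.0, 50.0
_TIME_MAP_CENTER_MASS = 1500.0
_TIME_MAP_SCALE = 0.55


def mass_to_time(mass: float | np.ndarray, jitter: float | np.ndarray = 0.0) -> np.ndarray:
    """Fixed monotone logistic map from neutral mass to the 19–50 min window."""
    m = np.asarray(mass, dtype=float)
    z = (np.log(m) - np.log(_TIME_MAP_CENTER_MASS)) / _TIME_MAP_SCALE
    t = TIME_LOW + (TIME_HIGH - TIME_LOW) / (1.0 + np.exp(-z))
    return np.clip(t + jitter, TIME_LOW, TIME_HIGH)


# ---------------------------------------------------------------------------
# operations


def calibrant_peptides(n: int = 10) -> list[TruePeptide]:
    """The fixed internal-standard peptides (always detected, effect 1)."""
    if not 1 <= n <= len(CALIBRANT_SEQUENCES):
        raise ValueError(f"n must be in [1, {len(CALIBRANT_SEQUENCES)}]")
    out = []
    for i, seq in enumerate(CALIBRANT_SEQUENCES[:n], start=1):
        mass = compute_peptide_mass(seq)
        out.append(
            TruePeptide(
                sequence=seq,
                parent_protein=f"CALIB{i:02d}",
                start_pos=1,
                end_pos=len(seq),
                true_mass=mass,
                true_time=float(mass_to_time(mass)),
                base_intensity=CALIBRANT_INTENSITY,
                is_calibrant=True,
            )
        )
    return out


def calibrant_reference(n: int = 10) -> pd.DataFrame:
    """Reference (mass, time, intensity) table for calibration."""
    cals = calibrant_peptides(n)
    return pd.DataFrame(
        {
            "mass_da": [c.true_mass for c in cals],
            "time_min": [c.true_time for c in cals],
            "intensity": [c.base_intensity for c in cals],
        }
    )


def build_peptide_universe(
    protein_db: Sequence[SeqRecord],
    n_background: int,
    seed: int | np.random.Generator = 0,
    umod_base_intensity: float = 8000.0,
) -> list[TruePeptide]:
    """Seven fixed Umod C-terminal fragments plus random background fragments.

    Background fragments are random in-protein substrings of length 8–40 with
    log-uniform base intensities over [1e2, 1e5]; sequences are unique across
    the universe so that every true peptide is a distinct feature.
    """
    if not protein_db:
        raise ValueError("protein database is empty")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    rng = np.random.default_rng(seed)
    umod = _find_umod(protein_db)
    umod_seq = str(umod.seq)

    peptides: list[TruePeptide] = []
    seen: set[str] = set()
    for start, end in UMOD_FRAGMENT_COORDS:
        seq = umod_seq[start - 1 : end]
        peptides.append(
            TruePeptide(
                sequence=seq,
                parent_protein=umod.id,
                start_pos=start,
                end_pos=end,
                true_mass=compute_peptide_mass(seq),
                true_time=0.0,  # assigned below
                base_intensity=umod_base_intensity,
            )
        )
        seen.add(seq)

    # background fragments come from the non-Umod entries, so the Umod
    # C-terminal set stays exactly the seven fixed fragments
    proteins = [(rec.id, str(rec.seq)) for rec in protein_db if rec.id != umod.id]
    if not proteins:
        proteins = [(umod.id, umod_seq)]
    attempts = 0
    while len(peptides) < n_background + len(UMOD_FRAGMENT_COORDS):
        attempts += 1
        if attempts > 50 * (n_background + 1):
            raise RuntimeError("could not draw enough unique background fragments")
        name, pseq = proteins[rng.integers(len(proteins))]
        length = int(rng.integers(8, 41))
        if len(pseq) < length:
            continue
        start = int(rng.integers(1, len(pseq) - length + 2))
        seq = pseq[start - 1 : start - 1 + length]
        if seq in seen:
            continue
        seen.add(seq)
        peptides.append(
            TruePeptide(
                sequence=seq,
                parent_protein=name,
                start_pos=start,
                end_pos=start + length - 1,
                true_mass=compute_peptide_mass(seq),
                true_time=0.0,
                base_intensity=float(10 ** rng.uniform(2, 5)),
            )
        )

    jitter = rng.uniform(-1.5, 1.5, size=len(peptides))
    for pep, j in zip(peptides, jitter):
        pep.true_time = float(mass_to_time(pep.true_mass, j))
    return peptides


def assign_effects(
    peptides: list[TruePeptide],
    scenario: str,
    seed: int | np.random.Generator = 0,
    hypertensive: str = DEFAULT_HYPERTENSIVE,
    umod_fold_gd12: float = 4.0,
    umod_fold_gd18: float = 8.0,
    background_differential_fraction: float = 0.10,
    background_log2fc_sd: float = 1.0,
    custom_factors: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
) -> list[TruePeptide]:
    """Attach per-(strain, time point) abundance factors in place.

    ``paper_like`` up-regulates every Umod fragment in the hypertensive strain
    by the same factor (4 at GD12, 8 at GD18, 1 at prepregnancy), so the
    summed-Umod hypertensive/control ratio equals those folds; a random
    fraction of background peptides receives pregnancy-dependent fold changes
    2**N(0, sd) at GD12 and GD18.  ``custom`` applies an explicit
    sequence -> {(strain, time point): factor} table.
    """
    rng = np.random.default_rng(seed)
    if scenario == "null":
        for pep in peptides:
            pep.effect_profile = {}
        return peptides
    if scenario == "custom":
        if custom_factors is None:
            raise ValueError("scenario 'custom' requires an explicit factor table")
        for pep in peptides:
            pep.effect_profile = dict(custom_factors.get(pep.sequence, {}))
            if pep.is_calibrant and pep.effect_profile:
                raise ValueError("calibrants cannot carry effects")
        return peptides
    if scenario != "paper_like":
        raise ValueError(f"unknown scenario {scenario!r}")

    for pep in peptides:
        pep.effect_profile = {}
        if pep.is_calibrant:
            continue
        if (
            "UMOD" in pep.parent_protein.upper()
            and UMOD_CTERM_START <= pep.start_pos <= pep.end_pos <= UMOD_CTERM_END
        ):
            pep.effect_profile = {
                (hypertensive, "GD12"): umod_fold_gd12,
                (hypertensive, "GD18"): umod_fold_gd18,
            }
        elif rng.random() < background_differential_fraction:
            fold = float(2.0 ** rng.normal(0.0, background_log2fc_sd))
            pep.effect_profile = {
                (hypertensive, "GD12"): fold,
                (hypertensive, "GD18"): fold,
            }
    return peptides


def build_design(
    n_animals: int = 7,
    strains: Sequence[str] = DEFAULT_STRAINS,
    time_points: Sequence[str] = DEFAULT_TIME_POINTS,
) -> pd.DataFrame:
    """Paired longitudinal design: every animal sampled at every time point."""
    rows = []
    for strain in strains:
        for a in range(1, n_animals + 1):
            animal = f"{strain}{a:02d}"
            for tp in time_points:
                rows.append(
                    {
                        "sample_id": f"{animal}_{tp}",
                        "animal_id": animal,
                        "strain": strain,
                        "time_point": tp,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "animal_id", "strain", "time_point"])


def simulate_sample(
    peptides: Sequence[TruePeptide],
    strain: str,
    time_point: str,
    model: MeasurementModel,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One sample's observed peak list (sorted by mass).

    Observed mass = true_mass · (1 + ε_ppm·1e-6); observed time =
    slope·true_time + intercept + time noise; observed intensity =
    base · effect · sample factor · mean-one log-normal noise.  Detection is
    Bernoulli with logistic probability in log-intensity; calibrants are
    always detected.
    """
    rng = np.random.default_rng(seed)
    n = len(peptides)
    true_mass = np.array([p.true_mass for p in peptides])
    true_time = np.array([p.true_time for p in peptides])
    base = np.array([p.base_intensity for p in peptides])
    effect = np.array([p.effect(strain, time_point) for p in peptides])
    is_cal = np.array([p.is_calibrant for p in peptides])

    eps_ppm = rng.normal(0.0, model.mass_error_sd, size=n) if model.mass_error_sd else np.zeros(n)
    t_noise = rng.normal(0.0, model.time_noise_sd, size=n) if model.time_noise_sd else np.zeros(n)
    if model.intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(model.intensity_cv**2)))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))  # mean one
    else:
        noise = np.ones(n)

    slope, intercept = model.time_drift
    mass = true_mass * (1.0 + eps_ppm * 1e-6)
    time = slope * true_time + intercept + t_noise
    intensity = base * effect * model.sample_intensity_factor * noise

    detect_u = rng.random(n)
    detected = detect_u < model.detection_probability(intensity)
    detected |= is_cal

    df = pd.DataFrame(
        {
            "mass_da": mass[detected],
            "time_min": time[detected],
            "intensity": intensity[detected],
        },
        columns=PEAK_COLUMNS,
    )
    return df.sort_values("mass_da", kind="mergesort").reset_index(drop=True)


def _ground_truth_table(
    peptides: Sequence[TruePeptide],
    strains: Sequence[str],
    hypertensive: str,
    time_points: Sequence[str],
) -> pd.DataFrame:
    control = next((s for s in strains if s != hypertensive), hypertensive)
    rows = []
    for pep in peptides:
        if pep.is_calibrant:
            continue
        row = {
            "sequence": pep.sequence,
            "parent_protein": pep.parent_protein,
            "start_pos": pep.start_pos,
            "end_pos": pep.end_pos,
            "true_mass": pep.true_mass,
            "true_time": pep.true_time,
            "base_intensity": pep.base_intensity,
        }
        for strain in strains:
            for tp in time_points:
                row[f"mean_{strain}_{tp}"] = pep.base_intensity * pep.effect(strain, tp)
        for tp in time_points:
            fc = pep.effect(hypertensive, tp) / pep.effect(control, tp)
            row[f"true_fc_{tp}"] = fc
            row[f"differential_{tp}"] = fc != 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def generate_study(config: StudyConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Simulate a complete study (all samples) from one root seed.

    The root seed fans out through ``numpy.random.SeedSequence`` children in a
    fixed order (universe, effects, sample factors/drifts, then one child per
    sample in design order), so any stage is independently reproducible.
    """
    config = config or StudyConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_universe, ss_effects, ss_study = root.spawn(3)

    protein_db = default_protein_db()
    peptides = build_peptide_universe(
        protein_db, config.n_background, np.random.default_rng(ss_universe)
    )
    peptides.extend(calibrant_peptides(config.n_calibrants))
    assign_effects(
        peptides,
        config.scenario,
        seed=np.random.default_rng(ss_effects),
        hypertensive=config.hypertensive,
        umod_fold_gd12=config.umod_fold_gd12,
        umod_fold_gd18=config.umod_fold_gd18,
        background_differential_fraction=config.background_differential_fraction,
        background_log2fc_sd=config.background_log2fc_sd,
    )

    design = build_design(config.n_animals, config.strains, config.time_points)
    study_rng = np.random.default_rng(ss_study)
    sample_seeds = root.spawn(len(design))

    dropout = (
        (config.dropout_midpoint, config.dropout_steepness)
        if config.dropout_enabled
        else None
    )
    peak_lists: dict[str, pd.DataFrame] = {}
    for (_, entry), child in zip(design.iterrows(), sample_seeds):
        slope = float(np.clip(study_rng.normal(1.0, config.drift_slope_sd), 0.95, 1.05))
        intercept = float(
            np.clip(study_rng.normal(0.0, config.drift_intercept_sd), -1.0, 1.0)
        )
        factor = float(np.exp(study_rng.normal(0.0, config.sample_intensity_sd)))
        model = MeasurementModel(
            time_drift=(slope, intercept),
            mass_error_sd=config.mass_error_sd,
            time_noise_sd=config.time_noise_sd,
            intensity_cv=config.intensity_cv,
            sample_intensity_factor=factor,
            dropout=dropout,
        )
        peak_lists[entry.sample_id] = simulate_sample(
            peptides,
            entry.strain,
            entry.time_point,
            model,
            seed=np.random.default_rng(child),
        )

    ground_truth = _ground_truth_table(
        peptides, config.strains, config.hypertensive, config.time_points
    )
    return SyntheticStudy(
        peak_lists=peak_lists,
        design=design,
        ground_truth=ground_truth,
        peptides=peptides,
        calibrant_reference=calibrant_reference(config.n_calibrants),
        protein_db=protein_db,
        config=config,
    )


def config_to_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d
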