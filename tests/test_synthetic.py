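import numpy as np
import pytest

from pepticlust.chemistry import compute_peptide_mass
from pepticlust import synthetic
from pepticlust.synthetic import (
    MeasurementModel,
    StudyConfig,
    TruePeptide,
    assign_effects,
    build_design,
    build_peptide_universe,
    calibrant_peptides,
    default_protein_db,
    generate_study,
    simulate_sample,
)


class TestPeptideUniverse:
    def test_umod_fragments_only(self, protein_db):
        peps = build_peptide_universe(protein_db, n_background=0, seed=0)
        assert len(peps) == 7
        for p in peps:
            assert p.parent_protein == synthetic.UMOD_NAME
            assert 592 <= p.start_pos <= p.end_pos <= 609

    def test_longest_fragment_is_the_cterm_18mer(self, protein_db):
        peps = build_peptide_universe(protein_db, n_background=0, seed=0)
        longest = max(peps, key=lambda p: len(p.sequence))
        assert longest.sequence == "SGNFIDQTRVLNLGPITR"
        assert (longest.start_pos, longest.end_pos) == (592, 609)

    def test_fragments_are_parent_substrings_with_consistent_mass(self, protein_db):
        parents = {r.id: str(r.seq) for r in protein_db}
        peps = build_peptide_universe(protein_db, n_background=50, seed=3)
        assert sum(not p.is_calibrant for p in peps) == 57
        for p in peps:
            assert p.end_pos - p.start_pos + 1 == len(p.sequence)
            assert parents[p.parent_protein][p.start_pos - 1 : p.end_pos] == p.sequence
            assert p.true_mass == pytest.approx(
                compute_peptide_mass(p.sequence), abs=1e-6
            )
            assert 19.0 <= p.true_time <= 50.0
            assert 8 <= len(p.sequence) <= 40 or p.parent_protein == synthetic.UMOD_NAME

    def test_missing_or_short_umod_rejected(self, protein_db):
        no_umod = [r for r in protein_db if "UMOD" not in r.id]
        with pytest.raises(ValueError, match="UMOD"):
            build_peptide_universe(no_umod, 0, seed=0)
        from pepticlust.io import make_record

        short = [make_record("UMOD_TRUNC", "ACDEFGHIK" * 20)]
        with pytest.raises(ValueError, match="UMOD_TRUNC"):
            build_peptide_universe(short, 0, seed=0)


class TestEffects:
    def test_null_scenario_all_factors_one(self, protein_db):
        peps = build_peptide_universe(protein_db, 30, seed=1)
        assign_effects(peps, "null")
        assert all(
            p.effect(s, t) == 1.0
            for p in peps
            for s in ("WKY", "SHRSP")
            for t in ("NP", "GD12", "GD18")
        )

    def test_paper_like_umod_summed_ratio(self, protein_db):
        peps = build_peptide_universe(protein_db, 30, seed=1)
        assign_effects(peps, "paper_like", seed=2)
        umod = [p for p in peps if p.parent_protein == synthetic.UMOD_NAME]

        def summed(strain, tp):
            return sum(p.base_intensity * p.effect(strain, tp) for p in umod)

        assert summed("SHRSP", "GD12") / summed("WKY", "GD12") == pytest.approx(4.0)
        assert summed("SHRSP", "GD18") / summed("WKY", "GD18") == pytest.approx(8.0)
        assert summed("SHRSP", "NP") / summed("WKY", "NP") == pytest.approx(1.0)

    def test_calibrants_never_carry_effects(self):
        cals = calibrant_peptides()
        assign_effects(cals, "paper_like", seed=0)
        assert all(c.effect("SHRSP", "GD18") == 1.0 for c in cals)

    def test_unknown_scenario_rejected(self, protein_db):
        peps = build_peptide_universe(protein_db, 0, seed=0)
        with pytest.raises(ValueError, match="scenario"):
            assign_effects(peps, "bogus")


def _one_peptide(true_time=30.0, base=1000.0):
    return TruePeptide(
        sequence="SAMPLEPEPK",
        parent_protein="X",
        start_pos=1,
        end_pos=10,
        true_mass=compute_peptide_mass("SAMPLEPEPK"),
        true_time=true_time,
        base_intensity=base,
    )


class TestSimulateSample:
    def test_noiseless_limit_reproduces_true_values(self):
        pep = _one_peptide()
        df = simulate_sample([pep], "WKY", "NP", MeasurementModel.noiseless(), seed=0)
        assert len(df) == 1
        assert df.mass_da[0] == pep.true_mass
        assert df.time_min[0] == pep.true_time
        assert df.intensity[0] == pep.base_intensity

    def test_same_seed_is_byte_identical(self, protein_db):
        peps = build_peptide_universe(protein_db, 40, seed=5)
        model = MeasurementModel()
        a = simulate_sample(peps, "WKY", "NP", model, seed=42)
        b = simulate_sample(peps, "WKY", "NP", model, seed=42)
        assert a.equals(b)

    def test_affine_drift_applied(self):
        pep = _one_peptide(true_time=30.0)
        model = MeasurementModel.noiseless()
        model.time_drift = (1.02, 0.5)
        df = simulate_sample([pep], "WKY", "NP", model, seed=0)
        assert df.time_min[0] == pytest.approx(31.1)

    def test_detection_probability_monotone_and_calibrants_kept(self):
        model = MeasurementModel()
        probs = model.detection_probability(np.logspace(0, 6, 40))
        assert np.all(np.diff(probs) >= 0)
        cals = calibrant_peptides()
        tiny = MeasurementModel(dropout=(1e12, 0.1))  # everything else drops out
        df = simulate_sample(cals, "WKY", "NP", tiny, seed=0)
        assert len(df) == len(cals)

    def test_invalid_drift_slope_rejected(self):
        with pytest.raises(ValueError):
            MeasurementModel(time_drift=(0.0, 0.0))


class TestGenerateStudy:
    def test_default_shape_is_42_samples(self, default_study):
        assert len(default_study.peak_lists) == 42
        design = default_study.design
        assert design.groupby(["strain", "time_point"]).size().eq(7).all()
        assert not design.duplicated(["animal_id", "time_point"]).any()
        assert design.groupby("animal_id")["strain"].nunique().eq(1).all()

    def test_minimal_design_single_sample(self):
        cfg = StudyConfig.noiseless(
            seed=0, n_animals=1, strains=("WKY",), hypertensive="WKY",
            time_points=("NP",), n_background=5,
        )
        study = generate_study(cfg)
        assert len(study.peak_lists) == 1

    def test_null_noiseless_equal_peak_counts(self, noiseless_null_study):
        counts = {len(df) for df in noiseless_null_study.peak_lists.values()}
        assert len(counts) == 1

    def test_ground_truth_covers_every_non_calibrant(self, default_study):
        n_non_cal = sum(not p.is_calibrant for p in default_study.peptides)
        assert len(default_study.ground_truth) == n_non_cal
        assert default_study.ground_truth.sequence.is_unique

    def test_config_validation_reports_fields(self):
        cfg = StudyConfig(n_animals=0, n_background=-1, scenario="nope")
        with pytest.raises(ValueError) as err:
            cfg.validate()
        msg = str(err.value)
        assert "n_animals" in msg and "n_background" in msg and "scenario" in msg

    def test_seed_determinism_of_whole_study(self):
        a = generate_study(StudyConfig(seed=9, n_background=30))
        b = generate_study(StudyConfig(seed=9, n_background=30))
        assert all(a.peak_lists[k].equals(b.peak_lists[k]) for k in a.peak_lists)
        assert a.ground_truth.equals(b.ground_truth)


def test_injected_fold_changes_recoverable_over_replicates(protein_db):
    """Empirical group-mean ratios converge to the injected effect factors."""
    peps = build_peptide_universe(protein_db, 0, seed=4)
    assign_effects(peps, "paper_like", seed=4)
    model = MeasurementModel(time_drift=(1.0, 0.0), dropout=None)
    rng = np.random.SeedSequence(2024).spawn(400)
    sums = {"SHRSP": [], "WKY": []}
    for strain, children in (("SHRSP", rng[:200]), ("WKY", rng[200:])):
        for child in children:
            df = simulate_sample(
                peps, strain, "GD18", model, seed=np.random.default_rng(child)
            )
            sums[strain].append(df.intensity.sum())
    ratio = np.mean(sums["SHRSP"]) / np.mean(sums["WKY"])
    assert ratio == pytest.approx(8.0, rel=0.03)


def test_design_builder_pairs_animals_longitudinally():
    design = build_design(n_animals=3)
    assert len(design) == 18
    assert design.groupby("animal_id").size().eq(3).all()
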