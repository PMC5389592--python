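import pytest

from pepticlust import annotation, calibration, clustering, stats, synthetic


@pytest.fixture(scope="session")
def protein_db():
    return synthetic.default_protein_db()


@pytest.fixture(scope="session")
def noiseless_null_study():
    """Noiseless study, no effects, no dropout: the oracle-identity regime."""
    cfg = synthetic.StudyConfig.noiseless(scenario="null", seed=101, n_background=60)
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def noiseless_paper_study():
    cfg = synthetic.StudyConfig.noiseless(scenario="paper_like", seed=102, n_background=60)
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """One default-noise study under the pregnancy-effect scenario."""
    return synthetic.generate_study(synthetic.StudyConfig(seed=7))


from helpers import run_through_matrix  # noqa: E402


@pytest.fixture(scope="session")
def default_matrix(default_study):
    return run_through_matrix(default_study)


@pytest.fixture(scope="session")
def default_results(default_study, default_matrix):
    matrix, _ = default_matrix
    return stats.run_differential(
        matrix, default_study.design, hypertensive=default_study.config.hypertensive
    )


@pytest.fixture(scope="session")
def default_annotations(default_study, default_matrix):
    _, summary = default_matrix
    candidates = annotation.candidate_table_from_ground_truth(default_study.ground_truth)
    return annotation.annotate_clusters(summary, candidates)
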