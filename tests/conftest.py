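import pytest

from cogannot import (
    ScoringScheme,
    SimulationConfig,
    build_reduced_db,
    generate_toy_cogdb,
    sample_reads,
)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_cfg():
    """Six-category fixture: 36 proteins, 40 error-free reads."""
    return SimulationConfig(n_categories=6, n_reads=40, seed=7)


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    db, xmap = generate_toy_cogdb(small_cfg)
    reads, truths = sample_reads(db, small_cfg)
    return db, xmap, reads, truths


@pytest.fixture(scope="session")
def small_reduced(small_fixture):
    db, _, _, _ = small_fixture
    return build_reduced_db(db)


@pytest.fixture(scope="session")
def full25_fixture():
    """All-25-category fixture at the generator's default conditions."""
    cfg = SimulationConfig(seed=7)
    db, xmap = generate_toy_cogdb(cfg)
    return cfg, db, xmap


@pytest.fixture(scope="session")
def full25_reduced(full25_fixture):
    _, db, _ = full25_fixture
    return build_reduced_db(db)
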