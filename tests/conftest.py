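import pytest

from famvar import pipeline as pl
from famvar import simulate as sim
from famvar.fixtures import table2_fixture


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced-size clean cohort bundle shared across unit tests."""
    out = tmp_path_factory.mktemp("bundle_small")
    cfg = sim.SimConfig(seed=7, n_background_sites=2_000)
    return sim.simulate_cohort(cfg, str(out))


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Pipeline outputs for the small bundle."""
    out = tmp_path_factory.mktemp("run_small")
    cfg = pl.config_for_bundle(small_bundle, str(out), seed=7)
    report = pl.run_all(cfg)
    return small_bundle, cfg, report


@pytest.fixture(scope="session")
def table2_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("table2")
    return table2_fixture(str(out))
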