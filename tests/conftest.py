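import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lmrnet.pipeline import PipelineConfig, run_pipeline
from lmrnet.sim import SimulationConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: frozen seed used for all regression-style assertions
SEED = 1


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_sim_config():
    """A light config exercising every feature class (fast to simulate)."""
    return SimulationConfig(
        n_genes=24,
        n_tfs=5,
        n_lncrnas=8,
        n_mirnas=6,
        planted_tf_edges=5,
        planted_mirna_edges=4,
        planted_lnc_cis_edges=2,
        planted_lnc_trans_edges=3,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return simulate(small_sim_config)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """End-to-end pipeline run under the study conditions (3x3 design,
    30/20/10/10 planted edges, 100 decoys, frozen seed), run twice for the
    determinism contract."""
    out_a = tmp_path_factory.mktemp("study_a")
    out_b = tmp_path_factory.mktemp("study_b")
    res_a = run_pipeline(
        PipelineConfig(outdir=out_a, seed=SEED, simulate=SimulationConfig())
    )
    res_b = run_pipeline(
        PipelineConfig(outdir=out_b, seed=SEED, simulate=SimulationConfig())
    )
    return res_a, res_b


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """Same design with target_correlation 0 and no planted motifs: the
    false-positive guard."""
    out = tmp_path_factory.mktemp("null")
    cfg = PipelineConfig(
        outdir=out,
        seed=SEED,
        simulate=SimulationConfig(target_correlation=0.0, plant_motifs=False),
    )
    return run_pipeline(cfg)
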