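import pytest
from hypothesis import HealthCheck, settings

from epiredist.genomic_io import GenomeLayout
from epiredist.pipeline import analyze
from epiredist.simulate import SimConfig, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic fixture: 2x10 Mb, 50 planted lost domains."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full in-memory pipeline run on the default fixture."""
    return analyze(default_sim)


@pytest.fixture(scope="session")
def small_sim_config():
    """A light fixture configuration for file-based / CLI round trips."""
    return SimConfig(
        seed=3,
        layout=GenomeLayout((("chr1", 4_000_000), ("chr2", 4_000_000))),
        n_genes=100,
        n_domains=10,
        n_gain_pro=24,
        n_gain_se=8,
        n_hdac1_loss=20,
        n_up_genes=12,
        n_shared_peaks=40,
        reads_per_track=1_000_000,
    )
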