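import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retromap.formats import GenomeRef
from retromap.synthetic import SimConfig, simulate_genome, synthetic_provirus

settings.register_profile(
    "fast",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def provirus():
    return synthetic_provirus(seed=7)


@pytest.fixture(scope="session")
def small_genome():
    """50 kb random single-chromosome genome without genes (fast mapping)."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=50_000))
    return GenomeRef(sequences={"chr1": seq})


@pytest.fixture(scope="session")
def annotated_genome():
    """3 x 1 Mb genome tiled with genes at the 4/39/57 target fractions."""
    config = SimConfig(
        seed=101,
        chromosome_lengths=(1_000_000, 1_000_000, 1_000_000),
        target_region_fractions=(0.04, 0.39, 0.57),
    )
    return simulate_genome(config), config
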