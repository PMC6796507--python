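import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from gcbias import (
    BiasFunction,
    GCLandscapeSpec,
    GenomeSequence,
    generate_genome,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    """A 10-kb synthetic genome with a mid-range GC gradient."""
    spec = GCLandscapeSpec(
        segments=((2_000, 0.30), (3_000, 0.45), (3_000, 0.55), (2_000, 0.65)),
        seed=11,
    )
    return generate_genome(spec, contig_id="g10k")


def random_genome(rng, length=10_000, contig_id="rand"):
    """Uniform-random ACGT genome, used by oracle-equivalence tests."""
    bases = rng.choice(list("ACGT"), size=length)
    return GenomeSequence(contig_id, "".join(bases))
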