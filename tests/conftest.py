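import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diphap.simulate import SimParams, simulate
from diphap.types import Contig

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_SCENE = dict(
    genome_bp=400_000,
    n_chroms=1,
    n_primary_contigs=4,
    n_haplotigs=3,
    haplotig_len_range=(40_000, 70_000),
    n_genes=20,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 400-kb single-chromosome scene: fast, fully truth-labeled."""
    return simulate(SimParams(seed=11, **SMALL_SCENE))


@pytest.fixture(scope="session")
def default_scene():
    """The reference study scene: 5 Mb over 2 chromosomes, 40 primary
    contigs, 25 haplotigs, 30 genes and 3 markers per allelic pair."""
    return simulate(SimParams(seed=1))


def random_haplotype(seed: int, length: int, name: str = "chr1") -> Contig:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Contig(name, bases[rng.integers(0, 4, size=length)].tobytes()
                  .decode())
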