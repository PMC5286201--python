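import numpy as np
import pytest

from pombesv import SVCall, SVType, SimulationSpec, plan_svs
from pombesv.synth import random_genome

ALL_TYPES = ["DEL", "DUP", "INS", "INV", "TRA"]


@pytest.fixture(scope="session")
def small_genome():
    """Three-chromosome 500 kb genome, deterministic."""
    return random_genome([200_000, 150_000, 150_000], gc=0.36, seed=11)


@pytest.fixture(scope="session")
def mixed_truth(small_genome):
    """A mixed-type truth set planned on the small genome."""
    spec = SimulationSpec(
        counts={t: n for t, n in zip(ALL_TYPES, [6, 4, 3, 3, 2])},
        size_ranges={t: (500, 2000) for t in ALL_TYPES},
        seed=5,
    )
    return plan_svs(small_genome, spec)


def make_call(
    id="c",
    type=SVType.DEL,
    chrom="chr1",
    start=1000,
    end=2000,
    caller="x",
    **kwargs,
):
    return SVCall(id=id, type=type, chrom=chrom, start=start, end=end, caller=caller, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
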