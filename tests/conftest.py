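import numpy as np
import pytest

from hypoxrna.core_io import CountMatrix
from hypoxrna.simulate import SimulationConfig, run_simulation
from hypoxrna import classify as cl
from hypoxrna import expression as ex

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """The full default study, genome included, at the package seed."""
    return run_simulation(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def tiny_sim():
    return run_simulation(SimulationConfig.tiny(seed=3))


@pytest.fixture(scope="session")
def default_expression(default_sim):
    """Filtered counts -> expression table for the default study."""
    sim = default_sim
    ann = sim.annotation
    classified = cl.classify_all([t.interval for t in ann], ann)
    classes = {tid: c for c, pairs in classified.assigned.items() for _, tid in pairs}
    public = CountMatrix(sim.counts.counts.loc[[t for t in sim.counts.transcript_ids
                                                if t in classes]])
    filtered = cl.filter_low_abundance(public, classes, cl.default_thresholds(ann))
    return ex.build_expression_table(filtered, classes)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=500):
    from hypoxrna.core_io import GenomicInterval

    out = []
    for _ in range(n):
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(
            chroms[int(rng.integers(len(chroms)))], start, start + length,
            "+" if rng.random() < 0.5 else "-"))
    return out
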