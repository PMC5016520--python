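import pytest

from clonostat.repertoire import filter_cdr3_range
from clonostat.simulate import SimConfig, generate_pair


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated pair with one strong injected shift."""
    config = SimConfig(
        n_clonotypes=(3000, 3000),
        effects={"IGHV4-34": 0.03},
        n_outliers=(1, 2),
        seed=42,
    )
    return generate_pair(config)


@pytest.fixture(scope="session")
def small_sets(small_pair):
    recs1, recs2 = small_pair
    return (
        filter_cdr3_range(recs1, label="S1"),
        filter_cdr3_range(recs2, label="S2"),
    )
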