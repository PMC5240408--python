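import numpy as np
import pytest
from hypothesis import settings

import tilechrom as tc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A tiny but non-trivial simulation: 3 chromosomes, ~3k windows."""
    return tc.SimConfig(
        chrom_names=("chr1", "chrX", "chrY"),
        chrom_lengths=(80_000, 50_000, 30_000),
        chrom_classes=("A", "X", "Y"),
        n_marks=4,
        n_states_true=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return tc.sim.generate_genome(small_cfg)


def make_track(values, spacing=50, chrom="chr1", sample_id="s"):
    values = np.asarray(values, dtype=float)
    pos = np.arange(values.size) * spacing
    return tc.ProbeTrack(sample_id, {chrom: (pos, values)})
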