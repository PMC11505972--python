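import random

import pytest

from sangermerge.seqio import Direction
from sangermerge.simulate import WalkingSimSpec, simulate_walking_reads


@pytest.fixture
def four_read_set():
    """The standard error-free walking fixture: 4 reads (F,R,F,R) over a
    2000-base reference, read length 800, overlaps in [200, 300]."""
    spec = WalkingSimSpec(
        reference_length=2000,
        read_length=800,
        overlap_range=(200, 300),
        directions=(Direction.F, Direction.R, Direction.F, Direction.R),
        seed=11,
    )
    return simulate_walking_reads(spec)


@pytest.fixture
def small_spec():
    """A fast small-geometry walking spec for property loops."""

    def make(seed, directions=(Direction.F, Direction.R, Direction.F), **kw):
        defaults = dict(
            reference_length=600,
            read_length=250,
            overlap_range=(60, 100),
            directions=directions,
            seed=seed,
        )
        defaults.update(kw)
        return simulate_walking_reads(WalkingSimSpec(**defaults))

    return make


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
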