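import numpy as np
import pytest

from coversize import CoverageTrack, Region, RegionSet


@pytest.fixture
def uniform_track():
    """100 kb nuclear sequence at exact depth 10."""
    return CoverageTrack({"nuc": np.full(100_000, 10, dtype=np.int64)})


@pytest.fixture
def organelle_track():
    """Nuclear sequence at 10x next to a short organelle at 100x."""
    return CoverageTrack(
        {
            "nuc": np.full(100, 10, dtype=np.int64),
            "pt": np.full(10, 100, dtype=np.int64),
        }
    )


@pytest.fixture
def nuc_regions():
    return RegionSet([Region("nuc", 0, 100, "g1")])


def random_track(rng, n_seqs=3, max_len=200, max_depth=30):
    """A seeded random coverage track for round-trip/property checks."""
    return CoverageTrack(
        {
            f"seq{i}": rng.integers(0, max_depth, size=rng.integers(1, max_len))
            for i in range(n_seqs)
        }
    )
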