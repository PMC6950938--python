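import numpy as np
import pytest

from tfiiic.genome import Domain, FETrack, GenomeLayout


@pytest.fixture
def tiny_layout():
    """Two partitioned autosomes plus one whole-domain X."""
    return GenomeLayout(
        chromosomes={"chrI": 10_000, "chrII": 8_000, "chrX": 6_000},
        domains=(
            Domain("chrI", 0, 3_000, "left_arm"),
            Domain("chrI", 3_000, 7_000, "center"),
            Domain("chrI", 7_000, 10_000, "right_arm"),
            Domain("chrII", 0, 2_500, "left_arm"),
            Domain("chrII", 2_500, 5_500, "center"),
            Domain("chrII", 5_500, 8_000, "right_arm"),
            Domain("chrX", 0, 6_000, "whole"),
        ),
        autosomes=frozenset({"chrI", "chrII"}),
    )


def track_from_dense(factor, arrays):
    return FETrack.from_dense(factor, {c: np.asarray(a, float) for c, a in arrays.items()})


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
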