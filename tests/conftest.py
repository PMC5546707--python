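import numpy as np
import pandas as pd
import pytest

from gsk.genome import GenomeLayout
from gsk.tracks import BinaryTrack, ScoreTrack


@pytest.fixture
def layout():
    return GenomeLayout(("chr1", "chr2"), {"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_score_track(layout, rng, n_runs=50):
    """Random disjoint scored runs on each chromosome."""
    runs = {}
    for chrom in layout.chromosomes:
        n = layout.lengths[chrom]
        cuts = np.sort(rng.choice(np.arange(1, n), size=2 * n_runs,
                                  replace=False))
        starts, ends = cuts[::2], cuts[1::2]
        values = rng.random(n_runs)
        runs[chrom] = (starts, ends, values)
    return ScoreTrack(layout, runs)


def random_binary_track(layout, rng, n_runs=30):
    iv = {}
    for chrom in layout.chromosomes:
        n = layout.lengths[chrom]
        cuts = np.sort(rng.choice(np.arange(1, n), size=2 * n_runs,
                                  replace=False))
        iv[chrom] = (cuts[::2], cuts[1::2])
    return BinaryTrack(layout, iv)


@pytest.fixture
def score_track(layout, rng):
    return random_score_track(layout, rng)
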