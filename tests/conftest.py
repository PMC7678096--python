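import numpy as np
import pandas as pd
import pytest

from trackfuse import CoverageTrack, ProbabilityTrack


def make_track(values, bin_size=10, chrom="chr1", cls=CoverageTrack, start=0):
    """Build a contiguous single-chromosome track from a value vector."""
    values = np.asarray(values, dtype=float)
    starts = start + np.arange(len(values)) * bin_size
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + bin_size, "value": values}
    )
    return cls(df, bin_size, [chrom])


def make_prob(values, **kw):
    return make_track(values, cls=ProbabilityTrack, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def prob_factory():
    return make_prob
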