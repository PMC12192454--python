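import numpy as np
import pytest

from karyoscreen import ArmInterval, CallerConfig, ScreenConfig, SegmentRecord

MB = 1_000_000


@pytest.fixture
def caller_cfg():
    return CallerConfig()


@pytest.fixture
def screen_cfg():
    return ScreenConfig()


@pytest.fixture
def arm_100mb():
    """A single arm spanning [0, 100 Mb)."""
    return ArmInterval(chromosome="1", arm="p", start=0, end=100 * MB)


def make_segment(sample="S1", chrom="1", start=0, end=MB, mean=0.0):
    return SegmentRecord(
        sample_id=sample, chromosome=chrom, start=start, end=end, seg_mean=mean
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1)
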