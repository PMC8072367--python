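import numpy as np
import pytest

from ece_screen.genome_model import ConservationTrack, GenomicInterval
from ece_screen.motif_scanner import pfm_to_pwm
from ece_screen.synthetic_data import gc_box_pfm


@pytest.fixture
def pfm():
    return gc_box_pfm()


@pytest.fixture
def pwm(pfm):
    return pfm_to_pwm(pfm)


def make_track(values, chrom="chrT", start=0):
    """Track from a plain list (None/NaN = missing)."""
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    region = GenomicInterval(chrom, start, start + arr.size)
    return ConservationTrack(region, arr)


@pytest.fixture
def track_factory():
    return make_track
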