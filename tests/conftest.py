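import numpy as np
import pytest

from tfscape.intervals import GenomicInterval, IntervalSet
from tfscape.simulate import LandscapeSpec, default_pwms, simulate_all


def random_interval_set(rng, n, n_chroms=2, max_pos=5000, max_len=120, label=""):
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs, label=label)


@pytest.fixture(scope="session")
def pwms():
    return default_pwms()


@pytest.fixture(scope="session")
def small_landscape():
    """One small fully-simulated landscape shared across read-only tests."""
    spec = LandscapeSpec(
        seed=20,
        n_peaks=200,
        n_footprints_fg=120,
        n_bg_regions=600,
        n_genes=120,
    )
    return simulate_all(spec)
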