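import numpy as np
import pytest

from svhotspots.detection import SV_TYPES, DetectionConfig, Peak, WindowTrack
from svhotspots.io import GenomicInterval


def make_track(counts, chrom="chr1", window=100_000, step=100_000, length=None):
    """WindowTrack with the given per-window distinct-sample counts.

    Sample names are globally unique per window so count_total reproduces
    ``counts`` exactly; all samples are filed under DUP.
    """
    counts = list(counts)
    length = length or (len(counts) - 1) * step + window
    windows = [
        GenomicInterval(chrom, i * step, min(i * step + window, length), f"w{i}")
        for i in range(len(counts))
    ]
    sample_sets = [{f"w{i}_s{j}" for j in range(c)} for i, c in enumerate(counts)]
    type_sets = {t: [set() for _ in counts] for t in SV_TYPES}
    type_sets["DUP"] = [set(s) for s in sample_sets]
    return WindowTrack(chrom, windows, sample_sets, type_sets)


def make_peak(start, end, samples, chrom="chr1", n_sv_samples=100, svtype="DUP"):
    """Single candidate Peak whose samples all carry ``svtype``."""
    samples = set(samples)
    type_samples = {t: set() for t in SV_TYPES}
    type_samples[svtype] = set(samples)
    return Peak(chrom, start, end, samples, type_samples, n_sv_samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cfg():
    return DetectionConfig()
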