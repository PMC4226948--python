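import numpy as np
import pytest

from apbskit import Genome, Interval, PeakSet


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture
def xyz_peaksets():
    """Three factors with the canonical staggered-overlap layout."""
    return [
        PeakSet("X", [Interval("chr1", 0, 400)]),
        PeakSet("Y", [Interval("chr1", 200, 600)]),
        PeakSet("Z", [Interval("chr1", 200, 400)]),
    ]


def per_base_membership(peaksets, chrom, length):
    """Brute-force per-base factor membership: boolean (n_factors, length)."""
    member = np.zeros((len(peaksets), length), dtype=bool)
    for fi, ps in enumerate(peaksets):
        for iv in ps:
            if iv.chrom == chrom:
                member[fi, iv.start:iv.end] = True
    return member


def random_peaksets(rng, n_factors, max_peaks, chrom_len):
    """Random small peak landscapes for oracle comparisons."""
    out = []
    for fi in range(n_factors):
        n = int(rng.integers(1, max_peaks + 1))
        ivs = []
        for _ in range(n):
            start = int(rng.integers(0, chrom_len - 10))
            end = int(start + rng.integers(1, min(500, chrom_len - start) + 1))
            ivs.append(Interval("chr1", start, end))
        out.append(PeakSet(f"F{fi}", ivs))
    return out
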