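import numpy as np
import pytest

from synercist.intervals import GenomicInterval, RegionSet

GENOME = {"chr1": 1_000_000, "chr2": 1_000_000}


def random_region_set(rng: np.random.Generator, n: int, label: str,
                      genome=None, max_len: int = 5000) -> RegionSet:
    genome = genome or GENOME
    chroms = sorted(genome)
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome[chrom] - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(
            GenomicInterval(chrom, start, start + length,
                            float(rng.random()), "none", f"{label}_{i}")
        )
    return RegionSet(label, ivs, genome)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
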