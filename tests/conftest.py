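import numpy as np
import pytest

from txstress.intervals import GenomeLayout, GenomicInterval, RegionSet


@pytest.fixture
def small_genome() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})


def random_regions(rng: np.random.Generator, genome: GenomeLayout, n: int,
                   max_len: int = 500, cls: bool = False) -> RegionSet:
    """Uniform random intervals for oracle-style comparisons."""
    ivs = []
    chroms = genome.chroms
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(genome.chrom_sizes[chrom] - length + 1))
        label = ("gain", "loss")[int(rng.integers(2))] if cls else None
        ivs.append(GenomicInterval(chrom, start, start + length, cnc_class=label))
    return RegionSet(ivs, genome)


def coverage_mask(regions: RegionSet, genome: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base boolean membership — the brute-force coverage oracle."""
    out = {c: np.zeros(l, dtype=bool) for c, l in genome.chrom_sizes.items()}
    for iv in regions:
        out[iv.chrom][iv.start:iv.end] = True
    return out
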