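import numpy as np
import pytest

from pta.coverage import CoverageTrack
from pta.intervals import GenomicInterval


class DenseOracle:
    """Brute-force per-base coverage arrays used as the independent oracle
    for every interval-counting operation."""

    def __init__(self, chrom_len: int):
        self.chrom_len = chrom_len
        self.arrays: dict[tuple[str, str], np.ndarray] = {}

    def add(self, chrom, strand, start, end, value):
        key = (chrom, strand)
        if key not in self.arrays:
            self.arrays[key] = np.zeros(self.chrom_len, dtype=np.int64)
        self.arrays[key][start:end] += value

    def count(self, iv: GenomicInterval) -> int:
        arr = self.arrays.get((iv.chrom, iv.strand))
        if arr is None:
            return 0
        return int(arr[iv.start : iv.end].sum())

    def track(self) -> CoverageTrack:
        return CoverageTrack.from_dense(self.arrays)


@pytest.fixture
def random_oracle():
    """Two-chromosome random step coverage plus its dense oracle."""

    def build(seed: int, n_intervals: int = 1000, chrom_len: int = 50_000):
        rng = np.random.default_rng(seed)
        oracle = DenseOracle(chrom_len)
        for _ in range(n_intervals):
            chrom = rng.choice(["chr1", "chr2"])
            strand = rng.choice(["+", "-"])
            start = int(rng.integers(0, chrom_len - 100))
            end = start + int(rng.integers(1, 100))
            oracle.add(chrom, strand, start, end, int(rng.integers(1, 10)))
        return oracle.track(), oracle

    return build


def track_from_bases(chrom, strand, base_counts: dict[int, int]) -> CoverageTrack:
    """Tiny track with explicit per-base counts."""
    if not base_counts:
        return CoverageTrack.from_steps({})
    positions = sorted(base_counts)
    starts = np.array(positions)
    return CoverageTrack.from_steps(
        {(chrom, strand): (starts, starts + 1,
                           np.array([base_counts[p] for p in positions]))}
    )


@pytest.fixture(scope="session")
def noiseless_study():
    """100-gene synthetic study with no background noise (shared: read-only)."""
    from pta.synth import default_study, generate_coverage

    specs, chrom_len = default_study(n_genes=100, seed=42, noise_rate=0.0)
    track, truth = generate_coverage(specs, chrom_len, seed=42)
    return track, truth


@pytest.fixture(scope="session")
def noisy_study():
    """100-gene study with background at 1% of the body rate."""
    from pta.synth import default_study, generate_coverage

    specs, chrom_len = default_study(n_genes=100, seed=43, noise_rate=0.005)
    track, truth = generate_coverage(specs, chrom_len, seed=43)
    return track, truth
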