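import numpy as np
import pytest

from g4snv.intervals import GenomicInterval, IntervalSet
from g4snv.simulate import SyntheticConfig, simulate_dataset


def random_interval_set(rng, n, n_chroms=2, coord_max=500, max_len=40):
    """Small random interval set for oracle comparisons."""
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, coord_max))
        end = start + int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs)


def brute_closest_value(query, references):
    """Exhaustive all-pairs signed nearest distance (None when no neighbour)."""
    best = None
    for ref in references:
        if ref.chrom != query.chrom:
            continue
        if query.start < ref.end and ref.start < query.end:
            d = 0
        elif query.end <= ref.start:
            d = -(ref.start - query.end)
        else:
            d = query.start - ref.end
        # tie between equal gaps left and right goes to the leftmost
        # reference, i.e. the one the query is downstream of (positive d)
        key = (abs(d), 0 if d >= 0 else 1)
        if best is None or key < best[0]:
            best = (key, d)
    return None if best is None else best[1]


def brute_intersect_counts(queries, references):
    return [sum(1 for r in references if q.overlaps(r)) for q in queries]


@pytest.fixture(scope="session")
def small_dataset():
    """One compact synthetic study shared by read-only tests."""
    cfg = SyntheticConfig(
        n_chroms=2,
        chrom_length=500_000,
        n_genes=10,
        n_g4=60,
        n_patients=80,
        n_dbsnv=4_000,
        seed=123,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240219)
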