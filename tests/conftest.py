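import numpy as np
import pytest
import scipy.sparse as sp

from epitrace.intervals import GenomicInterval
from epitrace.io import PeakMatrix


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def brute_force_overlaps(query, subject):
    """Quadratic all-pairs overlap oracle (half-open semantics)."""
    hits = set()
    for qi, q in enumerate(query):
        for s in subject:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                hits.add(qi)
                break
    return hits


def make_matrix(X, mode="single_cell", chrom="chr1", spacing=1000, width=500):
    X = np.asarray(X)
    peaks = [
        GenomicInterval(chrom, i * spacing, i * spacing + width)
        for i in range(X.shape[0])
    ]
    cells = [f"cell{i}" for i in range(X.shape[1])]
    return PeakMatrix(sp.csc_matrix(X), peaks, cells, mode=mode)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    # 6 peaks x 5 cells with assorted counts
    X = np.array(
        [
            [0, 1, 0, 2, 0],
            [3, 0, 0, 0, 1],
            [0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1],
            [0, 2, 4, 0, 0],
            [5, 0, 1, 1, 0],
        ]
    )
    return make_matrix(X)
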