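"""Total accessibility over clock-like loci (ClockAcc) and its entropy.

ClockAcc for a cell is the number of reference-overlapping peaks with
non-zero read coverage in that cell — the count of "opened" clock-like
loci. A cell accumulating mitoses homogenises accessibility over these
loci, so ClockAcc tracks mitotic age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .intervals import GenomicIntervalSet, overlap_indices
from .io import PeakMatrix


@dataclass
class ClockAccVector:
    """Per-cell count of opened reference-overlapping peaks."""

    values: np.ndarray
    n_reference_peaks: int
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.cell_ids):
            raise ValueError("one ClockAcc value per cell required")
        if np.any(self.values < 0):
            raise ValueError("ClockAcc values must be non-negative")


@dataclass
class EntropyResult:
    """Shannon entropy of the read distribution over reference peaks."""

    entropy: float
    p: np.ndarray
    base: str = "nats"


def reference_peaks(matrix: PeakMatrix, loci: GenomicIntervalSet) -> np.ndarray:
    """Indices of matrix peaks overlapping >= 1 clock-like locus.

    Raises ``ValueError`` if no peak overlaps the loci — the age
    estimate is undefined without a reference.
    """
    hits = overlap_indices(matrix.peak_intervals, loci)
    if not hits:
        raise ValueError(
            "no reference peaks overlap the clock-like loci; "
            "check chromosome naming and genome build"
        )
    return np.array(sorted(hits), dtype=int)


def compute_clockacc(
    matrix: PeakMatrix,
    ref_idx: np.ndarray,
    censor: bool = False,
    censor_quantile: float = 0.95,
) -> ClockAccVector:
    """Count opened reference peaks per cell.

    A peak is "opened" in a cell when its count is > 0. With
    ``censor=True``, counts are first winsorized per peak at the
    ``censor_quantile`` across cells before the > 0 test — a guard
    against aberrantly deep peaks; a peak open in fewer than
    ``1 - censor_quantile`` of cells is capped at zero and drops out.
    """
    ref_idx = np.asarray(ref_idx, dtype=int)
    if ref_idx.size == 0:
        raise ValueError("ref_idx must be non-empty")
    sub = matrix.counts[ref_idx, :]
    if censor:
        sub = sub.toarray().astype(float)
        caps = np.quantile(sub, censor_quantile, axis=1, keepdims=True)
        sub = np.minimum(sub, np.maximum(caps, 0.0))
        values = (sub > 0).sum(axis=0).astype(float)
    else:
        values = np.asarray((sub > 0).sum(axis=0)).ravel().astype(float)
    return ClockAccVector(values, n_reference_peaks=len(ref_idx), cell_ids=list(matrix.cell_ids))


def clock_entropy(
    matrix: PeakMatrix,
    ref_idx: np.ndarray,
    cell_subset: np.ndarray | None = None,
    base2: bool = False,
) -> EntropyResult:
    """Shannon entropy of summed reads over reference peaks.

    Per-peak reads (summed over ``cell_subset``, default all cells) are
    normalised to the grand total to give p(x); the entropy is
    ``-sum(p(x) * log(p(x)))`` with 0*log(0) := 0. Natural log by
    default; ``base2=True`` reports bits.
    """
    ref_idx = np.asarray(ref_idx, dtype=int)
    sub = matrix.counts[ref_idx, :]
    if cell_subset is not None:
        sub = sub[:, np.asarray(cell_subset, dtype=int)]
    per_peak = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    total = per_peak.sum()
    if total <= 0:
        raise ValueError("entropy undefined: zero total counts over reference peaks")
    p = per_peak / total
    nz = p > 0
    log = np.log2 if base2 else np.log
    entropy = float(-(p[nz] * log(p[nz])).sum())
    return EntropyResult(entropy=entropy, p=p, base="bits" if base2 else "nats")
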