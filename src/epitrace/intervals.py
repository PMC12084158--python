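"""Genomic interval containers and overlap queries.

All coordinates are 0-based half-open (BED convention). Inputs using
1-based single-position conventions (CpG site lists) are converted on
load by the readers in :mod:`epitrace.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name. No "chr" normalisation is attempted.
    start : int
        0-based inclusive start (bp). Must be >= 0.
    end : int
        Exclusive end (bp). Must be > start.
    strand : str
        One of ``+``, ``-`` or ``.`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def _key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def __lt__(self, other: "GenomicInterval") -> bool:
        return self._key() < other._key()

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomicIntervalSet:
    """An ordered, deduplicated collection of :class:`GenomicInterval`.

    Intervals are stored sorted by (chrom, start, end). Duplicates in the
    input are removed; the number removed is logged.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], name: str = "") -> None:
        raw = list(intervals)
        seen: dict = {}
        for iv in raw:
            seen.setdefault(iv._key(), iv)
        n_dup = len(raw) - len(seen)
        if n_dup:
            logger.info("GenomicIntervalSet %r: removed %d duplicate intervals", name, n_dup)
        self.intervals: list[GenomicInterval] = sorted(seen.values())
        self.name = name
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"GenomicIntervalSet({self.name!r}, n={len(self)})"

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        if self._index is None:
            idx: dict[str, list[list[int]]] = {}
            for iv in self.intervals:
                idx.setdefault(iv.chrom, [[], []])
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in idx.items()
            }
        return self._index


def _warn_disjoint_chroms(query: GenomicIntervalSet, subject: GenomicIntervalSet) -> None:
    if query.chroms and subject.chroms and not (query.chroms & subject.chroms):
        logger.warning(
            "query and subject interval sets share no chromosome names "
            "(query: %s..., subject: %s...); check genome builds and 'chr' prefixes",
            sorted(query.chroms)[:3],
            sorted(subject.chroms)[:3],
        )


def overlap_indices(
    query: Sequence[GenomicInterval] | GenomicIntervalSet,
    subject: GenomicIntervalSet,
) -> set[int]:
    """Indices of query intervals overlapping >= 1 subject interval.

    Overlap is half-open: abutting intervals ([100,200) vs [200,300)) do
    not overlap. Query may be any sequence of intervals (e.g. a peak list
    in file order); subject must be a :class:`GenomicIntervalSet`.
    """
    if isinstance(query, GenomicIntervalSet):
        _warn_disjoint_chroms(query, subject)
        q_iter: Sequence[GenomicInterval] = query.intervals
    else:
        q_iter = list(query)
    sidx = subject._chrom_index()
    hits: set[int] = set()
    # Per chromosome: subject sorted by start. Intervals in genomic data may
    # be nested, so a pure two-pointer sweep is unsafe; use cumulative max of
    # ends plus searchsorted on starts.
    cummax: dict[str, np.ndarray] = {
        c: np.maximum.accumulate(e) for c, (s, e) in sidx.items()
    }
    for qi, iv in enumerate(q_iter):
        if iv.chrom not in sidx:
            continue
        starts, _ends = sidx[iv.chrom]
        cm = cummax[iv.chrom]
        # candidates: subject.start < iv.end
        j = int(np.searchsorted(starts, iv.end, side="left"))
        if j == 0:
            continue
        # any subject among [0, j) with end > iv.start ?
        if cm[j - 1] > iv.start:
            # confirm (cummax can overshoot only if the max end is before
            # iv.start, which the check excludes; cummax > start guarantees
            # at least one interval with end > iv.start and start < iv.end)
            hits.add(qi)
    return hits
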