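"""Readers and writers for the standard exchange formats.

Formats handled here:

* BED (3+ columns, 0-based half-open) for peaks and clock-like loci;
* MatrixMarket coordinate triplets + peaks BED + barcode list, the
  de-facto scATAC exchange trio;
* fragments TSV (chrom, start, end, barcode[, count]; optionally gzipped);
* CpG beta matrix TSV (first column ``chrom:pos`` locus ids, one column
  per sample) with companion sample-metadata and coverage TSVs.

Peak order from the BED file is preserved in :class:`PeakMatrix` so matrix
rows stay aligned with the file; a sorted interval index is built
internally for overlap queries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .intervals import GenomicInterval, GenomicIntervalSet

logger = logging.getLogger(__name__)

_BED_HEADER_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """Malformed BED line (non-integer coordinate, end <= start, ...)."""


@dataclass
class PeakMatrix:
    """Sparse peaks x cells (or peaks x samples) non-negative count matrix.

    Attributes
    ----------
    counts : scipy.sparse.csc_matrix
        Non-negative counts, shape (n_peaks, n_cells). Row order follows
        ``peak_intervals`` (file order), not genomic order.
    peak_intervals : list of GenomicInterval
        One interval per matrix row, in row order.
    cell_ids : list of str
        Unique cell (or sample) identifiers, one per column.
    mode : {"single_cell", "bulk"}
    """

    counts: sp.csc_matrix
    peak_intervals: list[GenomicInterval]
    cell_ids: list[str]
    mode: str = "single_cell"

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape[0] != len(self.peak_intervals):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but "
                f"{len(self.peak_intervals)} peak intervals"
            )
        if self.counts.shape[1] != len(self.cell_ids):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but "
                f"{len(self.cell_ids)} cell ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.mode not in ("single_cell", "bulk"):
            raise ValueError(f"mode must be single_cell or bulk, got {self.mode!r}")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def peaks(self) -> GenomicIntervalSet:
        """Sorted, deduplicated view of the peak intervals (for queries)."""
        return GenomicIntervalSet(self.peak_intervals, name="peaks")

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)


@dataclass
class BetaMatrix:
    """CpG methylation fractions (loci x samples) with ages and coverage.

    ``beta`` values lie in [0, 1]; ``sample_ages`` are donor ages in
    years; ``coverage`` is the mean read depth per locus (used for the
    strict > 30x filter of the DNAm age model).
    """

    beta: np.ndarray
    locus_intervals: list[GenomicInterval]
    sample_ids: list[str]
    sample_ages: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.sample_ages = np.asarray(self.sample_ages, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        n_loci, n_samples = self.beta.shape
        if len(self.locus_intervals) != n_loci:
            raise ValueError(
                f"{len(self.locus_intervals)} loci but beta has {n_loci} rows"
            )
        if len(self.sample_ids) != n_samples or len(self.sample_ages) != n_samples:
            raise ValueError("sample_ids/sample_ages length must match beta columns")
        if self.coverage.shape != (n_loci,):
            raise ValueError("coverage must have one entry per locus")
        if np.nanmin(self.beta) < 0 or np.nanmax(self.beta) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if not np.all(np.isfinite(self.sample_ages)) or np.any(self.sample_ages < 0):
            raise ValueError("sample ages must be finite and >= 0")

    @property
    def n_loci(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def loci(self) -> GenomicIntervalSet:
        """Sorted, deduplicated view of the CpG positions (for queries)."""
        return GenomicIntervalSet(self.locus_intervals, name="cpg_loci")

    @property
    def locus_ids(self) -> list[str]:
        """1-based 'chrom:pos' ids, in row order."""
        return [f"{iv.chrom}:{iv.end}" for iv in self.locus_intervals]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bed(
    path: str | Path,
    name: str | None = None,
    one_based: bool = False,
) -> GenomicIntervalSet:
    """Read a BED (3+ column) file into a sorted, deduplicated interval set.

    Header lines starting with ``track``, ``browser`` or ``#`` are
    skipped. Set ``one_based=True`` for 1-based single-position lists
    (CpG site tables): start is decremented and end forced to start+1.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}, line {lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}, line {lineno}: non-integer coordinate"
                ) from exc
            if one_based:
                start, end = start - 1, start
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
    return GenomicIntervalSet(intervals, name=name or path.stem)


def _read_bed_ordered(path: str | Path) -> list[GenomicInterval]:
    """BED rows in file order (no sorting/dedup) — for matrix row alignment."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}, line {lineno}: expected >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(intervals: GenomicIntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_peak_matrix(
    mtx_path: str | Path,
    peaks_bed_path: str | Path,
    barcodes_path: str | Path,
    mode: str = "single_cell",
) -> PeakMatrix:
    """Assemble a PeakMatrix from MatrixMarket triplets + BED + barcodes.

    The MTX header dimensions must match the BED and barcode line counts;
    mismatches raise a ``ValueError`` naming all three cardinalities.
    """
    peaks = _read_bed_ordered(peaks_bed_path)
    with _open_text(barcodes_path) as fh:
        barcodes = [ln.strip() for ln in fh if ln.strip()]
    mat = sp.csc_matrix(scipy.io.mmread(str(mtx_path)))
    if mat.shape[0] != len(peaks) or mat.shape[1] != len(barcodes):
        raise ValueError(
            f"dimension mismatch: matrix {mat.shape[0]}x{mat.shape[1]}, "
            f"peaks: {len(peaks)} ≠ {mat.shape[0]}"
            if mat.shape[0] != len(peaks)
            else f"dimension mismatch: matrix {mat.shape[0]}x{mat.shape[1]}, "
            f"barcodes: {len(barcodes)} ≠ {mat.shape[1]}"
        )
    if mat.nnz == 0:
        logger.warning("matrix %s has no stored entries (all-zero)", mtx_path)
    return PeakMatrix(mat, peaks, barcodes, mode=mode)


def write_peak_matrix(matrix: PeakMatrix, mtx_path, peaks_bed_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.counts))
    write_bed(matrix.peak_intervals, peaks_bed_path)
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(matrix.cell_ids) + "\n")


def read_fragments(
    path: str | Path,
    peaks: GenomicIntervalSet | Sequence[GenomicInterval],
    mode: str = "single_cell",
) -> PeakMatrix:
    """Count fragments into peaks: counts[p, c] = fragments of barcode c
    overlapping peak p.

    A fragment overlapping k peaks contributes to all k. Accepts 4- or
    5-column TSV (chrom, start, end, barcode[, count]), optionally
    gzipped. Barcodes are ordered by first appearance.
    """
    peak_list = list(peaks)
    ncols = _n_fragment_cols(path)
    names = ["chrom", "start", "end", "barcode", "count"][: max(ncols, 4)]
    frags = pd.read_csv(path, sep="\t", header=None, comment="#", names=names)
    if "count" not in frags.columns:
        frags["count"] = 1
    if not np.issubdtype(frags["count"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric count field")
    if not (
        np.issubdtype(frags["start"].dtype, np.integer)
        and np.issubdtype(frags["end"].dtype, np.integer)
    ):
        raise ValueError(f"{path}: non-integer fragment coordinates")

    barcodes: list[str] = list(dict.fromkeys(frags["barcode"].astype(str)))
    bc_index = {b: i for i, b in enumerate(barcodes)}

    # Index peaks per chromosome for the sweep.
    by_chrom: dict[str, list[int]] = {}
    for pi, iv in enumerate(peak_list):
        by_chrom.setdefault(iv.chrom, []).append(pi)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for chrom, sub in frags.groupby("chrom", sort=False):
        pis = by_chrom.get(str(chrom))
        if not pis:
            continue
        starts = np.array([peak_list[p].start for p in pis])
        ends = np.array([peak_list[p].end for p in pis])
        for s, e, b, v in zip(sub["start"], sub["end"], sub["barcode"], sub["count"]):
            hit = (starts < e) & (ends > s)
            ci = bc_index[str(b)]
            for p in np.flatnonzero(hit):
                rows.append(pis[p])
                cols.append(ci)
                vals.append(float(v))
    counts = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(peak_list), max(len(barcodes), 1))
    ).tocsc()
    if not barcodes:
        barcodes = ["__no_fragments__"]
    return PeakMatrix(counts, peak_list, barcodes, mode=mode)


def _n_fragment_cols(path: str | Path) -> int:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 4


def _parse_locus_id(locus_id: str) -> GenomicInterval:
    """Parse a 'chrom:pos' (1-based CpG position) locus id."""
    chrom, pos = locus_id.rsplit(":", 1)
    p = int(pos)
    return GenomicInterval(chrom, p - 1, p)


def read_beta_matrix(
    beta_path: str | Path,
    meta_path: str | Path,
    coverage_path: str | Path,
) -> BetaMatrix:
    """Read a beta matrix TSV with sample-metadata and coverage companions.

    ``beta_path``: first column locus id "chrom:pos" (1-based CpG
    position), one column per sample. ``meta_path``: columns sample_id,
    age_years. ``coverage_path``: columns locus_id, mean_depth.
    """
    beta_df = pd.read_csv(beta_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    cov = pd.read_csv(coverage_path, sep="\t").set_index("locus_id")
    meta = meta.set_index("sample_id").loc[list(beta_df.columns)]
    coverage = cov["mean_depth"].reindex(beta_df.index).to_numpy(dtype=float)
    if np.isnan(coverage).any():
        missing = beta_df.index[np.isnan(coverage)][:3].tolist()
        raise ValueError(f"coverage missing for loci, e.g. {missing}")
    loci = [_parse_locus_id(lid) for lid in beta_df.index]
    return BetaMatrix(
        beta=beta_df.to_numpy(dtype=float),
        locus_intervals=loci,
        sample_ids=list(beta_df.columns),
        sample_ages=meta["age_years"].to_numpy(dtype=float),
        coverage=coverage,
    )


def write_beta_matrix(bm: BetaMatrix, beta_path, meta_path, coverage_path) -> None:
    locus_ids = bm.locus_ids  # 1-based chrom:pos
    pd.DataFrame(bm.beta, index=locus_ids, columns=bm.sample_ids).to_csv(
        beta_path, sep="\t", index_label="locus_id"
    )
    pd.DataFrame({"sample_id": bm.sample_ids, "age_years": bm.sample_ages}).to_csv(
        meta_path, sep="\t", index=False
    )
    pd.DataFrame({"locus_id": locus_ids, "mean_depth": bm.coverage}).to_csv(
        coverage_path, sep="\t", index=False
    )
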