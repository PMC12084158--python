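"""Orthology-guided cross-species mapping of promoter clock loci.

Without a whole-genome alignment chain, clock-like loci can still be
transferred between species through gene orthology: source-species
clock loci falling within a ±window of a gene's transcription start
site (TSS) mark that gene as carrying a promoter clock locus; the
promoters of its orthologs in the target species (or target peaks near
those ortholog TSSs) become putative clock-like loci there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .intervals import GenomicInterval, GenomicIntervalSet, overlap_indices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its strand-aware, width-1 TSS interval.

    For + strand genes the TSS is the gene start; for − strand genes it
    is the last base of the gene body (end − 1).
    """

    gene_id: str
    tss: GenomicInterval
    species: str = ""

    @classmethod
    def from_gene_body(
        cls, gene_id: str, chrom: str, start: int, end: int, strand: str, species: str = ""
    ) -> "GeneAnnotation":
        pos = start if strand == "+" else end - 1
        return cls(gene_id, GenomicInterval(chrom, pos, pos + 1, strand), species)


class OrthologTable:
    """Unique, non-self (source_gene, target_gene) pairs; many-to-many."""

    def __init__(self, pairs) -> None:
        uniq = []
        seen = set()
        for src, tgt in pairs:
            if src == tgt:
                raise ValueError(f"self-pair not allowed: {src!r}")
            if (src, tgt) not in seen:
                seen.add((src, tgt))
                uniq.append((str(src), str(tgt)))
        self.pairs: list[tuple[str, str]] = uniq

    def targets_of(self, source_gene: str) -> list[str]:
        return [t for s, t in self.pairs if s == source_gene]

    def __len__(self) -> int:
        return len(self.pairs)


def _promoter_window(tss: GenomicInterval, window: int) -> GenomicInterval:
    start = max(0, tss.start - window)
    return GenomicInterval(tss.chrom, start, tss.start + window + 1)


def promoter_clock_loci(
    loci: GenomicIntervalSet,
    genes: list[GeneAnnotation],
    window: int = 100,
) -> list[str]:
    """Gene ids whose ±window promoter interval overlaps >= 1 clock locus.

    The window is symmetric around the TSS ([tss − w, tss + w]
    inclusive, i.e. half-open [tss − w, tss + w + 1)), so only the TSS
    placement — not the strand — affects the result.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    windows = [_promoter_window(g.tss, window) for g in genes]
    hits = overlap_indices(windows, loci)
    return [genes[i].gene_id for i in sorted(hits)]


def map_clock_loci(
    source_promoter_genes: list[str],
    orthologs: OrthologTable,
    target_genes: list[GeneAnnotation],
    target_peaks: GenomicIntervalSet | None = None,
    window: int = 100,
) -> GenomicIntervalSet:
    """Map promoter clock loci to the target species through orthology.

    For every source gene carrying a promoter clock locus and having at
    least one ortholog, collect all target peaks within ±window of the
    ortholog TSS; when no peak set is supplied, the ±window promoter
    intervals themselves are returned. The result is deduplicated and
    independent of input order. Zero mapped loci is a warning, not an
    error.
    """
    if len(orthologs) == 0:
        raise ValueError("ortholog table is empty")
    tgt_by_id = {g.gene_id: g for g in target_genes}
    mapped: list[GenomicInterval] = []
    for src in source_promoter_genes:
        for tgt_id in orthologs.targets_of(src):
            gene = tgt_by_id.get(tgt_id)
            if gene is None:
                continue
            win = _promoter_window(gene.tss, window)
            if target_peaks is None:
                mapped.append(win)
            else:
                hits = overlap_indices(list(target_peaks), GenomicIntervalSet([win]))
                mapped.extend(target_peaks[i] for i in hits)
    if not mapped:
        logger.warning("no clock-like loci could be mapped to the target species")
    return GenomicIntervalSet(mapped, name="mapped_clock_loci")
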