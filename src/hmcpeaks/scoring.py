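"""Gene-level peak density (PPKM), coverage masking and gene grouping.

PPKM — peaks per kilobase of protein-coding sequence per million total
peaks — scores how densely enrichment peaks cover a gene:

    ppkm = n_gene / (coding_length / 1000) / (total_peaks / 1e6)

where n_gene counts peaks overlapping the gene body (introns included)
by default, while the normalising length is the summed CDS-exon length.
Genes are grouped into "void" (no peak touches any CDS exon), "high"
(ppkm >= threshold, default 10) or "neither"; a gene qualifying for both
(intronic peaks can drive PPKM without touching an exon) is labelled
high so the two groups stay disjoint.

Regions whose sequencing depth exceeds a threshold (default 50x) can be
masked: peaks overlapping such regions are discarded before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, GenomicInterval, Peak, ValidationError
from .elements import merge_pairs

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_THRESHOLD = 50.0
DEFAULT_PPKM_THRESHOLD = 10.0


@dataclass(frozen=True)
class CoverageMask:
    """Disjoint, sorted intervals where depth exceeds the threshold."""

    intervals: tuple[GenomicInterval, ...]
    threshold: float = DEFAULT_COVERAGE_THRESHOLD


@dataclass(frozen=True)
class PpkmRecord:
    gene_id: str
    peak_count: int
    coding_length: int
    ppkm: float
    group: str  # void | high | neither


def build_coverage_mask(
    coverage: list[tuple[GenomicInterval, float]],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> CoverageMask:
    """Mask of regions with depth strictly greater than `threshold`,
    merged per contig."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for interval, depth in coverage:
        if depth > threshold:
            by_contig.setdefault(interval.contig, []).append(
                (interval.start, interval.end)
            )
    intervals = tuple(
        GenomicInterval(contig, s, e)
        for contig in sorted(by_contig)
        for s, e in merge_pairs(by_contig[contig])
    )
    return CoverageMask(intervals, threshold)


def filter_peaks(peaks: list[Peak], mask: CoverageMask | None) -> list[Peak]:
    """Drop peaks overlapping any masked interval by >= 1 bp (order kept).

    A None mask passes everything through with a warning: the peak file
    is then assumed to be pre-filtered upstream.
    """
    if mask is None:
        logger.warning("no coverage mask supplied; peaks pass unfiltered")
        return list(peaks)
    masked = {}
    for iv in mask.intervals:
        masked.setdefault(iv.contig, []).append((iv.start, iv.end))
    out = []
    for peak in peaks:
        pairs = masked.get(peak.interval.contig, ())
        if any(s < peak.interval.end and peak.interval.start < e for s, e in pairs):
            continue
        out.append(peak)
    return out


class _PeakIndex:
    """Per-contig arrays of peak coordinates for vectorised overlap counts."""

    def __init__(self, peaks: list[Peak]):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_contig.setdefault(p.interval.contig, []).append(
                (p.interval.start, p.interval.end)
            )
        self._arrays = {
            c: (
                np.array([s for s, _ in v], dtype=np.int64),
                np.array([e for _, e in v], dtype=np.int64),
            )
            for c, v in by_contig.items()
        }

    def count_overlapping(self, contig: str, start: int, end: int) -> int:
        if contig not in self._arrays:
            return 0
        starts, ends = self._arrays[contig]
        return int(np.count_nonzero((starts < end) & (ends > start)))


def ppkm(
    gene: GeneModel,
    peaks: list[Peak],
    total_peaks: int,
    count_mode: str = "body",
) -> float:
    """PPKM of one gene given the peaks overlapping it and the library's
    total peak count."""
    if total_peaks <= 0:
        raise ValidationError("total_peaks must be > 0")
    if gene.coding_length <= 0:
        raise ValidationError(f"gene {gene.gene_id}: coding_length 0")
    index = _PeakIndex(peaks)
    n_gene = _count_gene_peaks(gene, index, count_mode)
    return n_gene / (gene.coding_length / 1000) / (total_peaks / 1e6)


def _count_gene_peaks(gene: GeneModel, index: _PeakIndex, count_mode: str) -> int:
    if count_mode == "body":
        return index.count_overlapping(gene.contig, gene.body.start, gene.body.end)
    if count_mode == "exon":
        # count peaks touching >= 1 exon; per-exon counts may double-count
        # a peak spanning two exons, so test each peak via the merged exons
        pairs = merge_pairs([(e.start, e.end) for e in gene.cds_exons])
        starts, ends = index._arrays.get(gene.contig, (np.empty(0), np.empty(0)))
        hit = np.zeros(len(starts), dtype=bool)
        for s, e in pairs:
            hit |= (starts < e) & (ends > s)
        return int(np.count_nonzero(hit))
    raise ValueError(f"count_mode must be body/exon, got {count_mode!r}")


def classify_genes(
    genes: list[GeneModel],
    peaks: list[Peak],
    threshold: float = DEFAULT_PPKM_THRESHOLD,
    count_mode: str = "body",
    total_peaks: int | None = None,
) -> list[PpkmRecord]:
    """Score every gene and assign it to exactly one group.

    `peaks` must already be coverage-filtered. total_peaks defaults to
    len(peaks) and is the PPKM normalising constant.
    """
    n_total = total_peaks if total_peaks is not None else len(peaks)
    index = _PeakIndex(peaks)
    records = []
    for gene in genes:
        n_gene = _count_gene_peaks(gene, index, count_mode)
        value = (
            n_gene / (gene.coding_length / 1000) / (n_total / 1e6)
            if n_total > 0
            else 0.0
        )
        exon_hits = _count_gene_peaks(gene, index, "exon")
        if value >= threshold:
            group = "high"
        elif exon_hits == 0:
            group = "void"
        else:
            group = "neither"
        records.append(
            PpkmRecord(gene.gene_id, n_gene, gene.coding_length, value, group)
        )
    return records


def records_to_dataframe(records: list[PpkmRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.peak_count, r.coding_length, r.ppkm, r.group)
            for r in records
        ],
        columns=["gene_id", "peak_count", "coding_length", "ppkm", "group"],
    )
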