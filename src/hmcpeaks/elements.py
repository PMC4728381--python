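"""Partition the genome into element classes and count bases per class.

The classes mirror the compartments of an enrichment-distribution table:
merged CDS exons, introns (gene-body bases not covered by any exon), and
strand-aware flank windows upstream of the TSS and downstream of the TES
at 1/5/10 kb. Flank windows are cumulative supersets (the 5 kb window
contains the 1 kb window), not disjoint annuli; base ownership priority is
CDS exons > introns > flanks, so a base inside any gene body is never
counted in a flank window. Intergenic bases beyond 10 kb belong to no
class and surface only in diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import ContigCatalog, GeneModel, GenomicInterval, ValidationError

ELEMENT_CLASSES: tuple[str, ...] = (
    "CDS_Exons",
    "Introns",
    "TSS_up_1kb",
    "TSS_up_5kb",
    "TSS_up_10kb",
    "TES_down_1kb",
    "TES_down_5kb",
    "TES_down_10kb",
)

DEFAULT_FLANK_SIZES: tuple[int, ...] = (1000, 5000, 10000)

# plain (start, end) pairs grouped by contig; all helpers below operate on
# sorted, merged lists of such pairs
IntervalSet = dict[str, list[tuple[int, int]]]


def merge_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into a sorted union."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(pairs):
        if start >= end:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract_pairs(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b; both inputs sorted and merged."""
    out: list[tuple[int, int]] = []
    j = 0
    for start, end in a:
        cursor = start
        while j < len(b) and b[j][1] <= cursor:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cursor:
                out.append((cursor, bs))
            cursor = max(cursor, be)
            if cursor >= end:
                break
            k += 1
        if cursor < end:
            out.append((cursor, end))
    return out


def total_length(iset: IntervalSet) -> int:
    return sum(e - s for pairs in iset.values() for s, e in pairs)


def _merge_set(intervals: list[GenomicInterval]) -> IntervalSet:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    return {c: merge_pairs(p) for c, p in by_contig.items()}


def _subtract_set(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    out = {}
    for contig, pairs in a.items():
        diff = subtract_pairs(pairs, b.get(contig, []))
        if diff:
            out[contig] = diff
    return out


# ---------------------------------------------------------------------------
# Per-gene geometry
# ---------------------------------------------------------------------------

def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Introns of one gene: gene body minus the exon union, as maximal
    intervals. A single-exon gene spanning its body has no introns."""
    exon_pairs = merge_pairs([(e.start, e.end) for e in gene.cds_exons])
    body_pairs = [(gene.body.start, gene.body.end)]
    return [
        GenomicInterval(gene.contig, s, e, gene.strand)
        for s, e in subtract_pairs(body_pairs, exon_pairs)
    ]


def flank_windows(
    gene: GeneModel,
    sizes: tuple[int, ...],
    side: str,
    contigs: ContigCatalog,
) -> dict[int, GenomicInterval]:
    """Strand-aware flank windows anchored at the TSS (upstream) or TES
    (downstream), clipped to the contig. Windows are nested: the window
    for a larger size contains every smaller one. Sizes fully clipped
    away (anchor at a contig edge) are omitted from the map.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be upstream/downstream, got {side!r}")
    if list(sizes) != sorted(sizes) or any(s <= 0 for s in sizes):
        raise ValidationError("flank sizes must be positive and ascending")
    contig_len = contigs[gene.contig]
    minus = gene.strand == "-"
    # upstream on + strand / downstream on - strand extends left of anchor
    left = (side == "upstream") != minus
    anchor = gene.tss if side == "upstream" else gene.tes
    windows: dict[int, GenomicInterval] = {}
    for size in sizes:
        if left:
            start, end = max(0, anchor - size), anchor
        else:
            start, end = anchor, min(contig_len, anchor + size)
        if start < end:
            windows[size] = GenomicInterval(gene.contig, start, end, gene.strand)
    return windows


# ---------------------------------------------------------------------------
# Genome-wide element map
# ---------------------------------------------------------------------------

@dataclass
class ElementMap:
    """Per-class interval unions and base totals over the whole genome."""

    intervals: dict[str, IntervalSet]
    total_bases: dict[str, int]
    contigs: ContigCatalog
    flank_sizes: tuple[int, ...] = DEFAULT_FLANK_SIZES
    metadata: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.intervals)

    def unassigned_bases(self) -> int:
        """Diagnostic: genome bases belonging to no element class."""
        per_contig: dict[str, list[tuple[int, int]]] = {
            c: [] for c in self.contigs
        }
        for iset in self.intervals.values():
            for contig, pairs in iset.items():
                per_contig.setdefault(contig, []).extend(pairs)
        assigned = sum(
            e - s
            for contig, pairs in per_contig.items()
            for s, e in merge_pairs(pairs)
        )
        return sum(self.contigs.values()) - assigned


def build_element_map(
    genes: list[GeneModel],
    contigs: ContigCatalog,
    sizes: tuple[int, ...] = DEFAULT_FLANK_SIZES,
) -> ElementMap:
    """Build the genome-wide element map from gene models.

    Exons of all genes are merged; introns exclude bases covered by an
    exon of ANY gene; flank windows exclude all gene-body bases. Flank
    windows from different genes (and the TSS vs TES side) may overlap
    each other and such bases count in both sides' totals.
    """
    for gene in genes:
        contigs.check(gene.body)

    exon_set = _merge_set([e for g in genes for e in g.cds_exons])
    body_set = _merge_set([g.body for g in genes])
    intron_set = _subtract_set(body_set, exon_set)

    intervals: dict[str, IntervalSet] = {
        "CDS_Exons": exon_set,
        "Introns": intron_set,
    }
    for side, tag in (("upstream", "TSS_up"), ("downstream", "TES_down")):
        per_size: dict[int, list[GenomicInterval]] = {s: [] for s in sizes}
        for gene in genes:
            for size, window in flank_windows(gene, sizes, side, contigs).items():
                per_size[size].append(window)
        for size in sizes:
            label = f"{tag}_{size // 1000}kb"
            intervals[label] = _subtract_set(_merge_set(per_size[size]), body_set)

    total_bases = {label: total_length(iset) for label, iset in intervals.items()}
    metadata = {
        "flank_sizes": list(sizes),
        "gene_bodies_removed_from_flanks": True,
        "nested_windows": "cumulative",
    }
    return ElementMap(intervals, total_bases, contigs, tuple(sizes), metadata)
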