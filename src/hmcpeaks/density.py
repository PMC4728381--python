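"""Assign peaks to element classes and compute tags-per-kilobase densities.

A peak touching any CDS-exon base counts only as exonic; failing that, a
peak touching any intron base counts only as intronic; only fully
intergenic peaks count against the flank windows they overlap. Because
nested flank windows are cumulative, a peak in a 1 kb window also counts
in the matching 5 kb and 10 kb windows (the default, "cumulative"
convention); the "disjoint" convention instead credits only the smallest
window the peak overlaps on each side.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .annotation_io import Peak, ValidationError
from .elements import ELEMENT_CLASSES, ElementMap, IntervalSet


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at `ndigits` decimals (report formatting)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _overlaps(iset: IntervalSet, contig: str, start: int, end: int) -> bool:
    pairs = iset.get(contig)
    if not pairs:
        return False
    # rightmost interval starting before `end`
    idx = bisect_right(pairs, (end,)) - 1
    return idx >= 0 and pairs[idx][1] > start


def assign_peak(
    peak: Peak, emap: ElementMap, criterion: str = "overlap"
) -> set[str]:
    """Element classes a peak is counted in (empty set if none).

    criterion "overlap" uses the whole peak interval (>= 1 bp overlap);
    "midpoint" reduces the peak to its midpoint base first.
    """
    contig = peak.interval.contig
    if contig not in emap.contigs:
        raise ValidationError(f"peak on unknown contig {contig!r}")
    start, end = peak.interval.start, peak.interval.end
    if criterion == "midpoint":
        mid = (start + end) // 2
        start, end = mid, mid + 1
    elif criterion != "overlap":
        raise ValueError(f"criterion must be overlap/midpoint, got {criterion!r}")

    if _overlaps(emap.intervals["CDS_Exons"], contig, start, end):
        return {"CDS_Exons"}
    if _overlaps(emap.intervals["Introns"], contig, start, end):
        return {"Introns"}
    return {
        label
        for label in emap.intervals
        if label not in ("CDS_Exons", "Introns")
        and _overlaps(emap.intervals[label], contig, start, end)
    }


@dataclass(frozen=True)
class DensityRow:
    element: str
    total_bases: int
    tag_count: int
    tags_per_kb: float  # rounded (half-up, 2 dp) report value

    @staticmethod
    def from_counts(element: str, total_bases: int, tag_count: int) -> "DensityRow":
        raw = tag_count / total_bases * 1000 if total_bases else 0.0
        return DensityRow(element, total_bases, tag_count, round_half_up(raw, 2))

    @property
    def density(self) -> float:
        """Unrounded tags per kilobase."""
        return self.tag_count / self.total_bases * 1000 if self.total_bases else 0.0


@dataclass
class DensityTable:
    rows: list[DensityRow]
    n_peaks_input: int
    n_peaks_unassigned: int

    def row(self, element: str) -> DensityRow:
        for r in self.rows:
            if r.element == element:
                return r
        raise KeyError(element)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (r.element, r.total_bases, r.tag_count, f"{r.tags_per_kb:.2f}")
                for r in self.rows
            ],
            columns=["Group", "Total_Bases", "Tag_Count", "Tags_per_Kb"],
        )
        unassigned = pd.DataFrame(
            [("Unassigned", 0, self.n_peaks_unassigned, "")],
            columns=df.columns,
        )
        return pd.concat([df, unassigned], ignore_index=True)


def density_table(
    peaks: list[Peak],
    emap: ElementMap,
    criterion: str = "overlap",
    window_counting: str = "cumulative",
) -> DensityTable:
    """Tag counts and tags/kb per element class, in fixed row order."""
    if not emap.intervals or not any(emap.total_bases.values()):
        raise ValidationError("element map is empty")
    if window_counting not in ("cumulative", "disjoint"):
        raise ValueError(f"window_counting: {window_counting!r}")

    order = [c for c in ELEMENT_CLASSES if c in emap.intervals] + [
        c for c in emap.intervals if c not in ELEMENT_CLASSES
    ]
    counts = {label: 0 for label in order}
    unassigned = 0
    for peak in peaks:
        classes = assign_peak(peak, emap, criterion)
        if not classes:
            unassigned += 1
            continue
        if window_counting == "disjoint" and classes - {"CDS_Exons", "Introns"}:
            # keep only the smallest window per side
            kept = set()
            for side in ("TSS_up", "TES_down"):
                side_hits = sorted(
                    (c for c in classes if c.startswith(side)),
                    key=order.index,
                )
                if side_hits:
                    kept.add(side_hits[0])
            classes = kept
        for label in classes:
            counts[label] += 1

    rows = [
        DensityRow.from_counts(label, emap.total_bases[label], counts[label])
        for label in order
    ]
    return DensityTable(rows, len(peaks), unassigned)


def exon_intron_ratio(table: DensityTable) -> float:
    """Unrounded exon density divided by unrounded intron density."""
    exon, intron = table.row("CDS_Exons"), table.row("Introns")
    if exon.total_bases <= 0 or intron.total_bases <= 0:
        raise ValidationError("exon/intron rows need total_bases > 0")
    if intron.density == 0:
        raise ValidationError("intron density is zero; ratio undefined")
    return exon.density / intron.density
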