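"""File formats and the genomic-interval data model.

All coordinates inside the package are 0-based half-open (BED-native).
GFF3 files (1-based, closed) are converted on read and write; nothing
downstream of this module ever sees 1-based coordinates.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

import pandas as pd

PathOrText = Union[str, Path, TextIO]

GO_ID_RE = re.compile(r"^GO:\d{7}$")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


def _open(source: PathOrText) -> TextIO:
    if isinstance(source, io.TextIOBase):
        return source
    return open(source, "r", encoding="utf-8")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic span, 0-based half-open.

    strand is '+', '-' or '.' (unstranded). Enrichment peaks are always
    unstranded; gene strand controls upstream/downstream orientation.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValidationError("interval contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: its body span and the ordered protein-coding exons.

    The body runs from transcription start to end; coding_length is the
    summed exon length (the paper-style "length of protein-coding DNA"
    used to normalise PPKM).
    """

    gene_id: str
    body: GenomicInterval
    cds_exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.cds_exons:
            raise ValidationError(f"gene {self.gene_id}: no CDS exons")
        prev_end = None
        for exon in self.cds_exons:
            if exon.contig != self.body.contig:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on contig {exon.contig}, "
                    f"body on {self.body.contig}"
                )
            if exon.start < self.body.start or exon.end > self.body.end:
                raise ValidationError(
                    f"gene {self.gene_id}: CDS {exon.start}-{exon.end} "
                    f"outside gene span {self.body.start}-{self.body.end}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end

    @property
    def contig(self) -> str:
        return self.body.contig

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def coding_length(self) -> int:
        return sum(len(e) for e in self.cds_exons)

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware)."""
        return self.body.start if self.strand != "-" else self.body.end

    @property
    def tes(self) -> int:
        """Transcription end position (strand-aware)."""
        return self.body.end if self.strand != "-" else self.body.start


@dataclass(frozen=True)
class Peak:
    """One enrichment location (a Table-4 style "tag"). Unstranded."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValidationError(f"peak score must be >= 0, got {self.score}")


class ContigCatalog(Mapping[str, int]):
    """Map contig id -> length in bp; every interval's contig must resolve."""

    def __init__(self, lengths: Mapping[str, int]):
        for contig, length in lengths.items():
            if length <= 0:
                raise ValidationError(f"contig {contig}: length {length} <= 0")
        self._lengths = dict(lengths)

    def __getitem__(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise ValidationError(f"unknown contig {contig!r}") from None

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def check(self, interval: GenomicInterval) -> None:
        if interval.end > self[interval.contig]:
            raise ValidationError(
                f"interval {interval.contig}:{interval.start}-{interval.end} "
                f"extends past contig end {self[interval.contig]}"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.rstrip(";").split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff_genes(source: PathOrText) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/CDS features with Parent links).

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    When a gene has several transcripts, the one with the longest total
    CDS is kept; ties break on transcript id for determinism.
    """
    genes: dict[str, dict] = {}          # gene_id -> {interval}
    transcripts: dict[str, str] = {}     # mRNA id -> gene id
    cds: dict[str, list[GenomicInterval]] = {}   # parent id -> exons
    gene_order: list[str] = []

    with _open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"GFF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"GFF line {lineno}: non-integer coordinate"
                ) from None
            if ftype not in ("gene", "mRNA", "CDS"):
                continue
            try:
                interval = GenomicInterval(contig, start1 - 1, end1, strand)
            except ValidationError as exc:
                raise ParseError(f"GFF line {lineno}: {exc}") from None
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ParseError(f"GFF line {lineno}: gene without ID")
                genes[gene_id] = {"interval": interval}
                gene_order.append(gene_id)
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ParseError(
                        f"GFF line {lineno}: mRNA needs ID and Parent"
                    )
                transcripts[tid] = parent
            else:  # CDS
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"GFF line {lineno}: CDS without Parent")
                cds.setdefault(parent, []).append(interval)

    # attach CDS lists to genes via their transcript (or directly)
    per_gene: dict[str, list[tuple[str, list[GenomicInterval]]]] = {}
    for parent, exons in cds.items():
        gene_id = transcripts.get(parent, parent)
        if gene_id not in genes:
            raise ValidationError(
                f"CDS parent {parent!r} does not resolve to a gene"
            )
        per_gene.setdefault(gene_id, []).append((parent, exons))

    models = []
    for gene_id in gene_order:
        candidates = per_gene.get(gene_id)
        if not candidates:
            continue  # non-coding gene records are skipped
        candidates.sort(key=lambda kv: (-sum(len(e) for e in kv[1]), kv[0]))
        exons = sorted(candidates[0][1], key=lambda e: e.start)
        models.append(
            GeneModel(
                gene_id=gene_id,
                body=genes[gene_id]["interval"],
                cds_exons=tuple(exons),
            )
        )
    return models


def write_gff_genes(genes: Iterable[GeneModel]) -> str:
    """Serialise gene models as GFF3 (inverse of :func:`read_gff_genes`)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        c, s = gene.contig, gene.strand
        lines.append(
            f"{c}\thmcpeaks\tgene\t{gene.body.start + 1}\t{gene.body.end}\t."
            f"\t{s}\t.\tID={gene.gene_id}"
        )
        tid = f"{gene.gene_id}.t1"
        lines.append(
            f"{c}\thmcpeaks\tmRNA\t{gene.body.start + 1}\t{gene.body.end}\t."
            f"\t{s}\t.\tID={tid};Parent={gene.gene_id}"
        )
        for i, exon in enumerate(gene.cds_exons, start=1):
            lines.append(
                f"{c}\thmcpeaks\tCDS\t{exon.start + 1}\t{exon.end}\t.\t{s}"
                f"\t0\tID={tid}.cds{i};Parent={tid}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed_peaks(source: PathOrText) -> list[Peak]:
    """Read peaks from BED3+ (coordinates kept 0-based half-open)."""
    peaks = []
    with _open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"BED line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"BED line {lineno}: non-integer coordinate"
                ) from None
            if start >= end:
                raise ValidationError(
                    f"BED line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(
                Peak(GenomicInterval(fields[0], start, end), name, score)
            )
    return peaks


def write_bed_peaks(peaks: Iterable[Peak]) -> str:
    lines = []
    for p in peaks:
        row = [p.interval.contig, str(p.interval.start), str(p.interval.end)]
        if p.name is not None or p.score is not None:
            row.append(p.name if p.name is not None else ".")
        if p.score is not None:
            row.append(f"{p.score:g}")
        lines.append("\t".join(row))
    return "\n".join(lines) + ("\n" if lines else "")


def read_coverage_bedgraph(
    source: PathOrText,
) -> list[tuple[GenomicInterval, float]]:
    """Read per-base coverage from a 4-column bedGraph.

    Overlapping records are rejected; adjacent records with equal depth
    are merged.
    """
    records = []
    with _open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"bedGraph line {lineno}: expected 4 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                depth = float(fields[3])
            except ValueError:
                raise ParseError(
                    f"bedGraph line {lineno}: non-numeric field"
                ) from None
            if depth < 0:
                raise ValidationError(
                    f"bedGraph line {lineno}: negative depth {depth}"
                )
            records.append((GenomicInterval(fields[0], start, end), depth))

    records.sort(key=lambda r: (r[0].contig, r[0].start))
    merged: list[tuple[GenomicInterval, float]] = []
    for interval, depth in records:
        if merged:
            prev, prev_depth = merged[-1]
            if prev.contig == interval.contig and interval.start < prev.end:
                raise ValidationError(
                    f"bedGraph records overlap at "
                    f"{interval.contig}:{interval.start}"
                )
            if (
                prev.contig == interval.contig
                and interval.start == prev.end
                and depth == prev_depth
            ):
                merged[-1] = (
                    GenomicInterval(prev.contig, prev.start, interval.end),
                    depth,
                )
                continue
        merged.append((interval, depth))
    return merged


# ---------------------------------------------------------------------------
# GO annotations & contig catalog
# ---------------------------------------------------------------------------

def read_go_annotations(source: PathOrText) -> dict[str, set[str]]:
    """Read a two-column TSV of (gene_id, GO id) into gene -> term set."""
    annotations: dict[str, set[str]] = {}
    with _open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"annotation line {lineno}: expected 2 columns"
                )
            gene_id, term = fields[0], fields[1]
            if not GO_ID_RE.match(term):
                raise ValidationError(
                    f"annotation line {lineno}: bad GO id {term!r}"
                )
            annotations.setdefault(gene_id, set()).add(term)
    return annotations


def write_go_annotations(annotations: Mapping[str, Iterable[str]]) -> str:
    lines = []
    for gene_id in sorted(annotations):
        for term in sorted(annotations[gene_id]):
            lines.append(f"{gene_id}\t{term}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_contig_catalog(source: PathOrText) -> ContigCatalog:
    """Read a two-column TSV of (contig id, length)."""
    lengths: dict[str, int] = {}
    with _open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"contig line {lineno}: expected 2 columns")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"contig line {lineno}: non-integer length"
                ) from None
    return ContigCatalog(lengths)


def write_contig_catalog(contigs: ContigCatalog) -> str:
    return "".join(f"{c}\t{contigs[c]}\n" for c in contigs)
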