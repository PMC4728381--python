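"""Synthetic inputs with the statistical structure the analysis assumes.

Generates a multi-contig genome of non-overlapping multi-exon genes, a
peak set placed class-wise with chosen per-kilobase intensities (the
default preset mimics an exon density about twice the intron density,
with decaying flank rates), GO annotations with planted group-specific
term enrichment, and replicated qPCR CT tables from the digestion model
with known efficiency and true modified fraction.

Every generator is a pure function of its spec: the seed is combined
with a per-generator stream id, so outputs are byte-identical across
runs and adding one generator never perturbs another's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import (
    ContigCatalog,
    GeneModel,
    GenomicInterval,
    ValidationError,
    write_gff_genes,
)
from .elements import (
    ElementMap,
    IntervalSet,
    build_element_map,
    merge_pairs,
    subtract_pairs,
    total_length,
)
from .qpcr import invert_fraction_to_delta_ct

_STREAMS = {"genome": 101, "peaks": 211, "go": 307, "qpcr": 401}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the toy genome; exon counts default to the 4-11 range
    seen in small multi-exon arthropod genes."""

    n_contigs: int = 5
    contig_length: int = 200_000
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (4, 11)
    exon_length_range: tuple[int, int] = (80, 400)
    intron_length_range: tuple[int, int] = (60, 500)
    intergenic_gap_range: tuple[int, int] = (500, 4000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_length_range",
                     "intron_length_range", "intergenic_gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name} must be positive and ordered")
        if self.n_contigs <= 0 or self.contig_length <= 0 or self.n_genes < 0:
            raise ValidationError("genome dimensions must be positive")


def simulate_genome_models(
    spec: GenomeSpec,
) -> tuple[list[GeneModel], ContigCatalog]:
    """Place non-overlapping genes left to right across the contigs."""
    rng = _rng(spec.seed, "genome")
    contigs = ContigCatalog(
        {f"ctg{i + 1}": spec.contig_length for i in range(spec.n_contigs)}
    )
    names = list(contigs)
    genes: list[GeneModel] = []
    contig_idx, cursor = 0, int(rng.integers(*_incl(spec.intergenic_gap_range)))
    while len(genes) < spec.n_genes:
        n_exons = int(rng.integers(*_incl(spec.exon_count_range)))
        exon_lens = rng.integers(*_incl(spec.exon_length_range), size=n_exons)
        intron_lens = rng.integers(
            *_incl(spec.intron_length_range), size=max(0, n_exons - 1)
        )
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        if cursor + gene_len > spec.contig_length:
            contig_idx += 1
            if contig_idx >= spec.n_contigs:
                raise ValidationError(
                    f"could only place {len(genes)}/{spec.n_genes} genes; "
                    "increase contig_length/n_contigs or shrink genes"
                )
            cursor = int(rng.integers(*_incl(spec.intergenic_gap_range)))
            # re-draw on the next contig with a fresh gene
            continue
        contig = names[contig_idx]
        exons, pos = [], cursor
        for i in range(n_exons):
            exons.append(
                GenomicInterval(contig, pos, pos + int(exon_lens[i]), strand)
            )
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        gene_id = f"gene{len(genes) + 1:04d}"
        genes.append(
            GeneModel(
                gene_id,
                GenomicInterval(contig, cursor, cursor + gene_len, strand),
                tuple(exons),
            )
        )
        cursor += gene_len + int(rng.integers(*_incl(spec.intergenic_gap_range)))
    return genes, contigs


def simulate_genome(spec: GenomeSpec) -> tuple[str, ContigCatalog]:
    """GFF3 text plus the contig catalog (deterministic given the seed)."""
    genes, contigs = simulate_genome_models(spec)
    return write_gff_genes(genes), contigs


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

#: per-kb intensities shaped like the observed genome-wide density table
#: (exon ~ 2x intron, decaying flank rates, sparse intergenic background)
TABLE4_LIKE_INTENSITY: dict[str, float] = {
    "exon": 0.61,
    "intron": 0.27,
    "flank_1kb": 0.08,
    "flank_5kb": 0.07,
    "flank_10kb": 0.05,
    "intergenic": 0.02,
}

PEAK_CLASSES = tuple(TABLE4_LIKE_INTENSITY)


@dataclass(frozen=True)
class PeakSpec:
    """Class-wise homogeneous peak placement.

    intensity: expected peaks per kb per class. When n_peaks is given the
    class counts are multinomial with weights intensity x class size;
    otherwise each class count is Poisson. hot_genes maps gene ids to an
    intensity multiplier applied over the gene body, planting
    high-density genes on top of the baseline.
    """

    intensity: dict[str, float] = field(
        default_factory=lambda: dict(TABLE4_LIKE_INTENSITY)
    )
    peak_length_range: tuple[int, int] = (50, 150)
    n_peaks: int | None = None
    hot_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.intensity) - set(PEAK_CLASSES)
        if unknown:
            raise ValidationError(f"unknown peak classes {sorted(unknown)}")
        if any(v < 0 for v in self.intensity.values()):
            raise ValidationError("intensities must be >= 0")
        lo, hi = self.peak_length_range
        if lo <= 0 or hi < lo:
            raise ValidationError("peak_length_range must be positive, ordered")


def _generation_regions(
    genes: list[GeneModel], contigs: ContigCatalog, emap: ElementMap
) -> dict[str, IntervalSet]:
    """Disjoint placement regions: exon, intron, flank annuli, intergenic."""
    def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
        out: dict[str, list[tuple[int, int]]] = {}
        for src in (a, b):
            for c, pairs in src.items():
                out.setdefault(c, []).extend(pairs)
        return {c: merge_pairs(p) for c, p in out.items()}

    def diff(a: IntervalSet, b: IntervalSet) -> IntervalSet:
        return {
            c: d
            for c, pairs in a.items()
            if (d := subtract_pairs(pairs, b.get(c, [])))
        }

    flank1 = union(emap.intervals["TSS_up_1kb"], emap.intervals["TES_down_1kb"])
    flank5 = union(emap.intervals["TSS_up_5kb"], emap.intervals["TES_down_5kb"])
    flank10 = union(
        emap.intervals["TSS_up_10kb"], emap.intervals["TES_down_10kb"]
    )
    regions = {
        "exon": emap.intervals["CDS_Exons"],
        "intron": emap.intervals["Introns"],
        "flank_1kb": flank1,
        "flank_5kb": diff(flank5, flank1),
        "flank_10kb": diff(flank10, flank5),
    }
    genome: IntervalSet = {c: [(0, contigs[c])] for c in contigs}
    occupied: IntervalSet = {}
    for reg in regions.values():
        occupied = union(occupied, reg)
    regions["intergenic"] = diff(genome, occupied)
    return regions


class _RegionSampler:
    """Uniform base sampling over an interval set; the peak is fitted
    around the sampled base without leaving its enclosing interval
    (shrinking to the interval if that is shorter than the peak)."""

    def __init__(self, region: IntervalSet):
        self._flat = [(c, s, e) for c in sorted(region) for s, e in region[c]]
        sizes = np.array([e - s for _, s, e in self._flat], dtype=np.int64)
        self._cum = np.cumsum(sizes)
        self.total = int(self._cum[-1]) if len(sizes) else 0

    def sample(self, rng: np.random.Generator, length: int) -> GenomicInterval:
        offset = int(rng.integers(self.total))
        idx = int(np.searchsorted(self._cum, offset, side="right"))
        contig, s, e = self._flat[idx]
        pos = s + offset - (int(self._cum[idx - 1]) if idx else 0)
        if e - s <= length:
            return GenomicInterval(contig, s, e)
        start = min(max(s, pos - length // 2), e - length)
        return GenomicInterval(contig, start, start + length)


def simulate_peaks(
    genes: list[GeneModel],
    contigs: ContigCatalog,
    spec: PeakSpec,
) -> str:
    """BED text of synthetic peaks (deterministic given the seed)."""
    rng = _rng(spec.seed, "peaks")
    emap = build_element_map(genes, contigs)
    regions = _generation_regions(genes, contigs, emap)
    kb = {cls: total_length(regions[cls]) / 1000 for cls in PEAK_CLASSES}
    weights = np.array(
        [spec.intensity.get(cls, 0.0) * kb[cls] for cls in PEAK_CLASSES]
    )
    if spec.n_peaks is not None:
        if weights.sum() == 0:
            raise ValidationError("all class intensities are zero")
        counts = rng.multinomial(spec.n_peaks, weights / weights.sum())
    else:
        counts = rng.poisson(weights)

    peaks: list[tuple[GenomicInterval, str]] = []
    for cls, count in zip(PEAK_CLASSES, counts):
        if count == 0 or total_length(regions[cls]) == 0:
            continue
        sampler = _RegionSampler(regions[cls])
        for _ in range(count):
            length = int(rng.integers(*_incl(spec.peak_length_range)))
            peaks.append((sampler.sample(rng, length), cls))

    gene_by_id = {g.gene_id: g for g in genes}
    for gene_id in sorted(spec.hot_genes):
        mult = spec.hot_genes[gene_id]
        gene = gene_by_id[gene_id]
        sampler = _RegionSampler(
            {gene.contig: [(gene.body.start, gene.body.end)]}
        )
        lam = (mult - 1) * spec.intensity.get("exon", 0.0) * len(gene.body) / 1000
        for _ in range(int(rng.poisson(max(0.0, lam)))):
            length = int(rng.integers(*_incl(spec.peak_length_range)))
            peaks.append((sampler.sample(rng, length), "hot"))

    peaks.sort(key=lambda pc: (pc[0].contig, pc[0].start, pc[0].end))
    lines = [
        f"{iv.contig}\t{iv.start}\t{iv.end}\tpk{i + 1:06d}|{cls}"
        for i, (iv, cls) in enumerate(peaks)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def simulate_go(
    high_genes: list[str],
    void_genes: list[str],
    planted: dict[str, tuple[float, float]],
    n_background_terms: int = 20,
    background_freq: float = 0.1,
    seed: int = 0,
) -> str:
    """Annotation TSV with group-specific planted terms.

    planted maps a GO id to (freq_high, freq_void): each gene of a group
    carries the term with the group's Bernoulli frequency. Background
    terms are assigned independently of group.
    """
    for term, (fh, fv) in planted.items():
        if not (0 <= fh <= 1 and 0 <= fv <= 1):
            raise ValidationError(f"{term}: frequencies must be in [0, 1]")
    rng = _rng(seed, "go")
    background = [f"GO:{9000000 + i + 1:07d}" for i in range(n_background_terms)]
    lines = []
    for genes, freq_idx in ((sorted(high_genes), 0), (sorted(void_genes), 1)):
        for gene in genes:
            for term in sorted(planted):
                if rng.random() < planted[term][freq_idx]:
                    lines.append(f"{gene}\t{term}")
            for term in background:
                if rng.random() < background_freq:
                    lines.append(f"{gene}\t{term}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSimSpec:
    """CT tables from the digestion model.

    true_fraction maps (locus, enzyme_pair, stage) to the modified
    fraction in (0, 1]. Untreated CTs are Normal(baseline_ct, sd); the
    treated mean is shifted by the model dCT = -log_(1+E)(fraction).
    """

    true_fraction: dict[tuple[str, str, str], float]
    efficiency: float = 0.95
    ct_noise_sd: float = 0.15
    n_replicates: int = 4
    baseline_ct: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, f in self.true_fraction.items():
            if not (0 < f <= 1):
                raise ValidationError(f"{key}: fraction {f} outside (0, 1]")
        if self.ct_noise_sd < 0 or self.efficiency <= 0:
            raise ValidationError("need sd >= 0 and efficiency > 0")


def simulate_qpcr(spec: QpcrSimSpec) -> tuple[str, str]:
    """(CT table CSV, standard-curve CSV), deterministic given the seed.

    The standard curve is generated noiselessly from the spec
    efficiency, so fitting it recovers E exactly.
    """
    rng = _rng(spec.seed, "qpcr")
    ct_lines = ["locus,assay,stage,replicate,treatment,ct"]
    for key in sorted(spec.true_fraction):
        locus, pair, stage = key
        delta = invert_fraction_to_delta_ct(
            spec.true_fraction[key], spec.efficiency
        )
        for treatment, mean in (("mock", spec.baseline_ct),
                                ("digested", spec.baseline_ct + delta)):
            cts = mean + rng.normal(0.0, spec.ct_noise_sd, spec.n_replicates)
            for rep, ct in enumerate(cts, start=1):
                ct_lines.append(
                    f"{locus},{pair},{stage},{rep},{treatment},{float(ct)!r}"
                )
    slope = -1.0 / np.log10(1.0 + spec.efficiency)
    curve_lines = ["assay,relative_input,ct"]
    pairs = sorted({key[1] for key in spec.true_fraction})
    for pair in pairs:
        for dilution in (1.0, 0.1, 0.01):
            ct = float(spec.baseline_ct + slope * np.log10(dilution))
            curve_lines.append(f"{pair},{dilution},{ct!r}")
    return "\n".join(ct_lines) + "\n", "\n".join(curve_lines) + "\n"
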