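"""Run the whole analysis end to end with a reproducibility manifest.

Stages run in order: element map -> peak density -> PPKM gene grouping
-> GO-term comparison. Every intermediate table is written as TSV with a
commented header naming the tool version and config hash; the manifest
records input checksums, per-stage row counts and output checksums, so
a rerun with identical config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation_io import (
    ValidationError,
    read_bed_peaks,
    read_contig_catalog,
    read_coverage_bedgraph,
    read_gff_genes,
    read_go_annotations,
    write_bed_peaks,
)
from .density import density_table
from .elements import build_element_map
from .go_compare import compare_terms, results_to_dataframe
from .scoring import build_coverage_mask, classify_genes, filter_peaks, records_to_dataframe

logger = logging.getLogger(__name__)

STAGES = ("elements", "density", "ppkm", "go-compare")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    gff: str
    peaks: str
    contigs: str
    out_dir: str
    coverage: str | None = None
    go_annotations: str | None = None
    cov_threshold: float = 50.0
    ppkm_threshold: float = 10.0
    p_high: float = 0.01
    p_void: float = 0.05
    count_mode: str = "body"
    criterion: str = "overlap"
    window_counting: str = "cumulative"
    flank_sizes: tuple[int, ...] = (1000, 5000, 10000)

    def validate(self) -> None:
        for label, path in (
            ("gff", self.gff), ("peaks", self.peaks), ("contigs", self.contigs),
            ("coverage", self.coverage), ("go_annotations", self.go_annotations),
        ):
            if path is not None and not Path(path).is_file():
                raise ValidationError(f"{label} path not found: {path}")
        for name in ("cov_threshold", "ppkm_threshold", "p_high", "p_void"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def hash(self) -> str:
        """Digest of the analysis parameters plus input-file content.

        File *paths* and the output directory are excluded so a rerun on
        byte-identical inputs hashes the same wherever they live.
        """
        payload = asdict(self)
        for key in ("gff", "peaks", "contigs", "coverage",
                    "go_annotations", "out_dir"):
            payload.pop(key)
        payload["input_sha256"] = [
            _sha256(p)
            for p in (self.gff, self.peaks, self.contigs,
                      self.coverage, self.go_annotations)
            if p is not None
        ]
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_table(df, path: Path, config_hash: str) -> int:
    header = f"# hmcpeaks {__version__} config={config_hash}\n"
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(header)
        df.to_csv(handle, sep="\t", index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = config.hash()
    manifest: dict = {
        "tool": "hmcpeaks",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config_hash,
        "inputs": {
            label: {"path": path, "sha256": _sha256(path)}
            for label, path in (
                ("gff", config.gff),
                ("peaks", config.peaks),
                ("contigs", config.contigs),
                ("coverage", config.coverage),
                ("go_annotations", config.go_annotations),
            )
            if path is not None
        },
        "stages": [],
        "outputs": {},
    }

    genes = read_gff_genes(config.gff)
    contigs = read_contig_catalog(config.contigs)
    peaks = read_bed_peaks(config.peaks)
    if config.coverage is not None:
        mask = build_coverage_mask(
            read_coverage_bedgraph(config.coverage), config.cov_threshold
        )
        peaks = filter_peaks(peaks, mask)
    else:
        peaks = filter_peaks(peaks, None)

    def record(stage: str, n_rows: int, started: float) -> None:
        manifest["stages"].append(
            {"name": stage, "rows": n_rows,
             "seconds": round(time.monotonic() - started, 3)}
        )
        logger.info("stage %s done (%d rows)", stage, n_rows)

    # elements
    t0 = time.monotonic()
    try:
        emap = build_element_map(genes, contigs, config.flank_sizes)
        totals = pd.DataFrame(
            [(label, emap.total_bases[label]) for label in emap.intervals],
            columns=["Group", "Total_Bases"],
        )
        n = _write_table(totals, out_dir / "element_totals.tsv", config_hash)
        for label, iset in emap.intervals.items():
            bed = "".join(
                f"{c}\t{s}\t{e}\n" for c in sorted(iset) for s, e in iset[c]
            )
            (out_dir / f"elements_{label}.bed").write_text(bed)
    except Exception as exc:
        raise StageError("elements", exc) from exc
    record("elements", n, t0)

    # density
    t0 = time.monotonic()
    try:
        table = density_table(
            peaks, emap, config.criterion, config.window_counting
        )
        n = _write_table(
            table.to_dataframe(), out_dir / "density.tsv", config_hash
        )
        (out_dir / "peaks_filtered.bed").write_text(write_bed_peaks(peaks))
    except Exception as exc:
        raise StageError("density", exc) from exc
    record("density", n, t0)

    # ppkm
    t0 = time.monotonic()
    try:
        records = classify_genes(
            genes, peaks, config.ppkm_threshold, config.count_mode
        )
        ppkm_df = records_to_dataframe(records)
        n = _write_table(ppkm_df, out_dir / "ppkm.tsv", config_hash)
    except Exception as exc:
        raise StageError("ppkm", exc) from exc
    record("ppkm", n, t0)

    # go-compare
    if config.go_annotations is not None:
        t0 = time.monotonic()
        try:
            annotations = read_go_annotations(config.go_annotations)
            high = {r.gene_id for r in records if r.group == "high"}
            void = {r.gene_id for r in records if r.group == "void"}
            results = compare_terms(high, void, annotations)
            go_df = results_to_dataframe(results, config.p_high, config.p_void)
            n = _write_table(go_df, out_dir / "go_comparison.tsv", config_hash)
        except Exception as exc:
            raise StageError("go-compare", exc) from exc
        record("go-compare", n, t0)

    for path in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.bed")):
        manifest["outputs"][path.name] = _sha256(str(path))
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=list) + "\n"
    )
    return manifest
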