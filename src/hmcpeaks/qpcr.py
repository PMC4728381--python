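"""Percent 5-mC / 5-hmC from methylation-sensitive restriction qPCR.

A locus is digested with a modification-sensitive enzyme (or mock
treated), then amplified by qPCR. Unmodified sites are cut and stop
amplifying, so the CT shift between digested and mock DNA encodes the
fraction of cleavage-protected (modified) molecules:

    percent = 100 / (1 + E) ** dCT,   dCT = mean(CT_digested) - mean(CT_mock)

E is the per-cycle amplification efficiency as a fraction (E = 1 means
perfect doubling), estimated from a dilution standard curve:
E = 10 ** (-1 / slope) - 1 with slope the least-squares slope of CT on
log10(relative input). Three enzyme configurations are supported:
MspI/HpaII and TaqI/HpyF30I report CpG methylation at CCGG and TCGA
sites respectively, and T4-BGT glucosylation followed by Epi-MspI
reports 5-hmC at CCGG sites. Each assay reports what its enzyme pair
can see; no cross-assay deconvolution of 5-mC vs 5-hmC is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean

import numpy as np
import pandas as pd

from .annotation_io import ValidationError

# enzyme pair -> (recognition site, modification reported)
ASSAY_TABLE: dict[str, tuple[str, str]] = {
    "MspI/HpaII": ("CCGG", "5mC_CpG_CCGG"),
    "TaqI/HpyF30I": ("TCGA", "5mC_CpG_TCGA"),
    "T4-BGT+EpiMspI": ("CCGG", "5hmC_CCGG"),
}

MIN_REPLICATES = 4
EFFICIENCY_RANGE = (0.6, 1.2)


@dataclass(frozen=True)
class StandardCurve:
    """Dilution series fit: CT regressed on log10(relative input)."""

    points: tuple[tuple[float, float], ...]  # (relative_input, ct_mean)
    slope: float
    efficiency: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    enzyme_pair: str

    def __post_init__(self) -> None:
        if self.enzyme_pair not in ASSAY_TABLE:
            raise ValidationError(
                f"unknown enzyme pair {self.enzyme_pair!r}; "
                f"known: {sorted(ASSAY_TABLE)}"
            )

    @property
    def site(self) -> str:
        return ASSAY_TABLE[self.enzyme_pair][0]

    @property
    def modification_reported(self) -> str:
        return ASSAY_TABLE[self.enzyme_pair][1]


@dataclass(frozen=True)
class QpcrAssay:
    """One measurement: CT replicates for digested and mock aliquots of a
    locus, with the assay's standard curve."""

    assay: AssayDefinition
    locus: str
    ct_treated: tuple[float, ...]
    ct_untreated: tuple[float, ...]
    curve: StandardCurve | None
    stage: str | None = None

    def __post_init__(self) -> None:
        if not self.ct_treated or not self.ct_untreated:
            raise ValidationError(
                f"{self.locus}/{self.assay.name}: empty CT replicate list"
            )
        for ct in (*self.ct_treated, *self.ct_untreated):
            if not (0 < ct < 45):
                raise ValidationError(
                    f"{self.locus}/{self.assay.name}: CT {ct} outside (0, 45)"
                )


@dataclass(frozen=True)
class ModificationResult:
    locus: str
    assay_name: str
    delta_ct: float
    percent: float
    flags: tuple[str, ...] = ()
    stage: str | None = None


def fit_standard_curve(
    points: list[tuple[float, float]]
) -> StandardCurve:
    """Fit efficiency from a dilution series of >= 3 distinct inputs."""
    inputs = [p[0] for p in points]
    if len(set(inputs)) < 3:
        raise ValidationError("standard curve needs >= 3 distinct dilutions")
    if min(inputs) <= 0:
        raise ValidationError("relative inputs must be > 0")
    x = np.log10(inputs)
    y = np.array([p[1] for p in points], dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    if slope >= 0:
        raise ValidationError(
            f"standard-curve slope {slope:.3f} >= 0: no amplification"
        )
    efficiency = 10 ** (-1 / slope) - 1
    warnings = ()
    lo, hi = EFFICIENCY_RANGE
    if not (lo <= efficiency <= hi):
        warnings = (f"efficiency {efficiency:.3f} outside [{lo}, {hi}]",)
    return StandardCurve(tuple((float(a), float(b)) for a, b in points),
                         slope, float(efficiency), warnings)


def modification_percent(assay: QpcrAssay) -> ModificationResult:
    """Percent modified sites at the assay's locus, clamped to [0, 100]."""
    if assay.curve is None:
        raise ValidationError(
            f"{assay.locus}/{assay.assay.name}: no standard curve"
        )
    delta_ct = fmean(assay.ct_treated) - fmean(assay.ct_untreated)
    flags = list(assay.curve.warnings)
    if min(len(assay.ct_treated), len(assay.ct_untreated)) < MIN_REPLICATES:
        flags.append(f"fewer than {MIN_REPLICATES} replicates")
    percent = 100.0 / (1.0 + assay.curve.efficiency) ** delta_ct
    if delta_ct < 0:
        percent = 100.0
        flags.append("negative delta-CT (treated amplified earlier than mock)")
    return ModificationResult(
        assay.locus, assay.assay.name, delta_ct, percent,
        tuple(flags), assay.stage,
    )


def batch_report(assays: list[QpcrAssay]) -> pd.DataFrame:
    """One row per (locus, assay, stage) with mean and sd of percent
    across biological-replicate measurements."""
    if not assays:
        return pd.DataFrame(
            columns=["locus", "assay", "stage", "n", "percent_mean",
                     "percent_sd", "flags"]
        )
    results = [modification_percent(a) for a in assays]
    rows = {}
    for r in results:
        key = (r.locus, r.assay_name, r.stage)
        rows.setdefault(key, []).append(r)
    out = []
    for (locus, assay_name, stage), group in sorted(
        rows.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
    ):
        percents = np.array([r.percent for r in group])
        flags = sorted({f for r in group for f in r.flags})
        out.append(
            (
                locus, assay_name, stage, len(group),
                float(percents.mean()),
                float(percents.std(ddof=1)) if len(group) > 1 else 0.0,
                ";".join(flags),
            )
        )
    return pd.DataFrame(
        out,
        columns=["locus", "assay", "stage", "n", "percent_mean",
                 "percent_sd", "flags"],
    )


def assays_from_frames(
    ct: pd.DataFrame, curves: pd.DataFrame
) -> list[QpcrAssay]:
    """Build assays from the tabular interchange format.

    `ct` columns: locus, assay, stage, replicate, treatment
    {digested, mock}, ct. `curves` columns: assay, relative_input, ct.
    The assay column holds the enzyme-pair name.
    """
    fitted = {
        name: fit_standard_curve(list(zip(grp["relative_input"], grp["ct"])))
        for name, grp in curves.groupby("assay")
    }
    assays = []
    keys = ["locus", "assay", "stage"] if "stage" in ct.columns else ["locus", "assay"]
    for key, grp in ct.groupby(keys, dropna=False, sort=True):
        locus, pair = key[0], key[1]
        stage = key[2] if len(key) > 2 and pd.notna(key[2]) else None
        treated = tuple(grp.loc[grp["treatment"] == "digested", "ct"])
        mock = tuple(grp.loc[grp["treatment"] == "mock", "ct"])
        if pair not in fitted:
            raise ValidationError(f"no standard curve for assay {pair!r}")
        assays.append(
            QpcrAssay(
                AssayDefinition(pair, pair), locus, treated, mock,
                fitted[pair], stage,
            )
        )
    return assays


def invert_fraction_to_delta_ct(fraction: float, efficiency: float) -> float:
    """dCT that the digestion model predicts for a true modified fraction:
    dCT = -log(fraction) / log(1 + E). Used by the simulator."""
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction {fraction} outside (0, 1]")
    return -math.log(fraction) / math.log(1 + efficiency)
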