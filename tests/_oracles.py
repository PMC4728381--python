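"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's interval machinery: element
classes are computed per base with boolean arrays, Fisher p-values by
exact rational enumeration, so agreement is evidence and not tautology.
"""

from fractions import Fraction
from math import comb

import numpy as np


def per_base_masks(genes, contigs, sizes=(1000, 5000, 10000)):
    """label -> {contig: boolean per-base membership array}."""
    def blank():
        return {c: np.zeros(contigs[c], dtype=bool) for c in contigs}

    exon, body = blank(), blank()
    for g in genes:
        body[g.contig][g.body.start:g.body.end] = True
        for e in g.cds_exons:
            exon[g.contig][e.start:e.end] = True
    masks = {
        "CDS_Exons": exon,
        "Introns": {c: body[c] & ~exon[c] for c in contigs},
    }
    for side in ("TSS_up", "TES_down"):
        for size in sizes:
            m = blank()
            for g in genes:
                length = contigs[g.contig]
                if side == "TSS_up":
                    anchor, left = (
                        (g.body.start, True)
                        if g.strand != "-"
                        else (g.body.end, False)
                    )
                else:
                    anchor, left = (
                        (g.body.end, False)
                        if g.strand != "-"
                        else (g.body.start, True)
                    )
                if left:
                    m[g.contig][max(0, anchor - size):anchor] = True
                else:
                    m[g.contig][anchor:min(length, anchor + size)] = True
            masks[f"{side}_{size // 1000}kb"] = {
                c: m[c] & ~body[c] for c in contigs
            }
    return masks


def masks_from_element_map(emap):
    """Convert the package's interval-set map to per-base arrays."""
    out = {}
    for label, iset in emap.intervals.items():
        arrs = {c: np.zeros(emap.contigs[c], dtype=bool) for c in emap.contigs}
        for contig, pairs in iset.items():
            for s, e in pairs:
                arrs[contig][s:e] = True
        out[label] = arrs
    return out


def assign_peak_oracle(peak, masks):
    """Per-base re-derivation of the class-assignment rule."""
    c = peak.interval.contig
    s, e = peak.interval.start, peak.interval.end
    if masks["CDS_Exons"][c][s:e].any():
        return {"CDS_Exons"}
    if masks["Introns"][c][s:e].any():
        return {"Introns"}
    return {
        label
        for label in masks
        if label not in ("CDS_Exons", "Introns") and masks[label][c][s:e].any()
    }


def fisher_exact_fraction(a, b, c, d, tie_reltol=Fraction(1, 10**7)):
    """Two-sided Fisher p as an exact rational, by enumeration."""
    n1, n2, k = a + b, c + d, a + c
    total = comb(n1 + n2, k)
    probs = {
        x: Fraction(comb(n1, x) * comb(n2, k - x), total)
        for x in range(max(0, k - n2), min(k, n1) + 1)
    }
    cutoff = probs[a] * (1 + tie_reltol)
    return min(sum(p for p in probs.values() if p <= cutoff), Fraction(1))
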