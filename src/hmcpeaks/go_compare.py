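"""GO-term frequency comparison between two gene groups.

For each GO term seen in both groups, a 2x2 contingency of annotated vs
non-annotated genes across the groups is tested with a two-sided Fisher
exact test (sum of hypergeometric probabilities of all same-margin
tables no more likely than the observed one, with a 1e-7 relative tie
tolerance — the convention of R's fisher.test). Selection applies the
asymmetric raw-p cut-offs: 0.01 for terms enriched in the
hydroxymethylated ("high") group and 0.05 for terms enriched in the
peak-void group. Benjamini-Hochberg q-values are reported as an extra
column but never used for selection. Terms are used exactly as
annotated; GO ancestry is not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_io import ValidationError

DEFAULT_P_HIGH = 0.01
DEFAULT_P_VOID = 0.05
_TIE_RELTOL = 1e-7


@dataclass(frozen=True)
class TermContingency:
    """Counts for one term: a/b in group High with/without the term,
    c/d likewise in group Void."""

    term: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"{self.term}: negative cell count")
        if self.a < 1 or self.c < 1:
            raise ValidationError(
                f"{self.term}: term must be detected in both groups"
            )


@dataclass(frozen=True)
class TermResult:
    term: str
    a: int
    b: int
    c: int
    d: int
    freq_high: float
    freq_void: float
    enrichment_ratio: float
    p_value: float
    bh_q: float
    direction: str  # high-enriched | void-enriched | none


@dataclass(frozen=True)
class _PlainTable:
    """2x2 cell counts without the both-groups detection requirement."""

    a: int
    b: int
    c: int
    d: int


def build_contingencies(
    high: set[str],
    void: set[str],
    annotations: Mapping[str, Iterable[str]],
) -> list[TermContingency]:
    """One contingency per GO term detected in both groups."""
    if high & void:
        raise ValidationError("high and void gene groups overlap")
    if not high or not void:
        raise ValidationError("both gene groups must be non-empty")
    counts: dict[str, list[int]] = {}
    for group_idx, group in enumerate((high, void)):
        for gene in group:
            for term in set(annotations.get(gene, ())):
                counts.setdefault(term, [0, 0])[group_idx] += 1
    out = []
    for term in sorted(counts):
        a, c = counts[term]
        if a >= 1 and c >= 1:
            out.append(TermContingency(term, a, len(high) - a, c, len(void) - c))
    return out


def fisher_two_sided(
    t: TermContingency | tuple[int, int, int, int]
) -> float:
    """Two-sided Fisher exact p-value for one 2x2 table.

    Enumerates the hypergeometric distribution over all tables sharing
    the observed margins and sums the probabilities of those at most as
    likely as the observed table (relative tolerance 1e-7 on the
    comparison, so exact probability ties are always included). Accepts
    a TermContingency or a plain (a, b, c, d) tuple.
    """
    if not isinstance(t, TermContingency):
        a, b, c, d = t
        if min(a, b, c, d) < 0:
            raise ValidationError("negative cell count")
        t = _PlainTable(a, b, c, d)
    n_high, n_void, k = t.a + t.b, t.c + t.d, t.a + t.c
    if n_high + n_void == 0:
        return 1.0  # empty table: only itself is possible
    dist = hypergeom(n_high + n_void, n_high, k)
    support = np.arange(max(0, k - n_void), min(k, n_high) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(t.a)
    p = float(pmf[pmf <= p_obs * (1 + _TIE_RELTOL)].sum())
    # summing the full support accumulates ~1e-16 float error per term;
    # snap to the exact boundary rather than report p marginally below 1
    if p > 1.0 - 1e-9:
        return 1.0
    return p


def compare_terms(
    high: set[str],
    void: set[str],
    annotations: Mapping[str, Iterable[str]],
) -> list[TermResult]:
    """Test every both-group term; BH q over the tested family."""
    tables = build_contingencies(high, void, annotations)
    if not tables:
        return []
    pvals = [fisher_two_sided(t) for t in tables]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for t, p, q in zip(tables, pvals, qvals):
        freq_high = t.a / (t.a + t.b)
        freq_void = t.c / (t.c + t.d)
        ratio = freq_high / freq_void
        if ratio > 1:
            direction = "high-enriched"
        elif ratio < 1:
            direction = "void-enriched"
        else:
            direction = "none"
        results.append(
            TermResult(
                t.term, t.a, t.b, t.c, t.d,
                freq_high, freq_void, ratio, p, float(q), direction,
            )
        )
    return results


def select_terms(
    results: list[TermResult],
    p_high: float = DEFAULT_P_HIGH,
    p_void: float = DEFAULT_P_VOID,
) -> tuple[list[TermResult], list[TermResult]]:
    """Apply the asymmetric raw-p cut-offs; each list sorted by the
    high/void frequency ratio, descending (treemap-style area scaling
    uses this ratio)."""
    high_list = sorted(
        (r for r in results if r.direction == "high-enriched" and r.p_value <= p_high),
        key=lambda r: -r.enrichment_ratio,
    )
    void_list = sorted(
        (r for r in results if r.direction == "void-enriched" and r.p_value <= p_void),
        key=lambda r: -r.enrichment_ratio,
    )
    return high_list, void_list


def results_to_dataframe(
    results: list[TermResult],
    p_high: float = DEFAULT_P_HIGH,
    p_void: float = DEFAULT_P_VOID,
) -> pd.DataFrame:
    high_list, void_list = select_terms(results, p_high, p_void)
    selected = {r.term for r in high_list} | {r.term for r in void_list}
    return pd.DataFrame(
        [
            (
                r.term, r.a, r.b, r.c, r.d,
                r.freq_high, r.freq_void, r.enrichment_ratio,
                r.p_value, r.bh_q, r.direction, r.term in selected,
            )
            for r in results
        ],
        columns=[
            "term", "a", "b", "c", "d", "freq_high", "freq_void",
            "ratio", "p", "q", "direction", "selected",
        ],
    )
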