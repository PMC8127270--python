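"""Gene proximity to elements, expression categories, Fisher tests and GO
enrichment.

Genes within a 50-kbp window up- and downstream of an element are related
to the element's expressed status; gene expression is partitioned into
four RPKM categories ([0,1) not, [1,10) low, [10,100) medium, [100,inf)
high — half-open on the left so boundary values are assigned exactly
once); category differences between genes near expressed and near
not-expressed elements are tested by two-sided Fisher's exact tests with
BH-FDR, and GO over-representation in genes near expressed elements by
one-sided Fisher's exact tests with BH-FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneModel, LTRElement

CATEGORIES = ("not", "low", "medium", "high")
_BOUNDS = (1.0, 10.0, 100.0)


@dataclass
class ProximityRecord:
    gene_id: str
    element_id: str
    distance: int            # bp; 0 iff the intervals overlap
    element_expressed: bool


@dataclass
class EnrichmentResult:
    term: str
    count_selection: int
    count_background: int
    n_selection: int
    n_background: int
    p_value: float
    fdr: float
    enriched: bool


def genes_near_elements(genes: list[GeneModel], elements: list[LTRElement],
                        window: int = 50_000,
                        expressed: set[str] | None = None
                        ) -> list[ProximityRecord]:
    """One record per (gene, element) pair whose intervals overlap after
    extending the element by `window` on both sides.  The distance is the
    gap between the unextended intervals (0 on overlap)."""
    expressed = expressed or set()
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, i)
    out: list[ProximityRecord] = []
    for el in elements:
        tree = trees.get(el.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(el.start - window, el.end + window)):
            g = genes[iv.data]
            if g.end <= el.start:
                dist = el.start - g.end
            elif el.end <= g.start:
                dist = g.start - el.end
            else:
                dist = 0
            out.append(ProximityRecord(g.id, el.id, dist,
                                       el.id in expressed))
    out.sort(key=lambda r: (r.element_id, r.gene_id))
    return out


def genes_near_elements_bruteforce(genes: list[GeneModel],
                                   elements: list[LTRElement],
                                   window: int = 50_000,
                                   expressed: set[str] | None = None
                                   ) -> list[ProximityRecord]:
    """Quadratic scan with the same contract, for cross-checking."""
    expressed = expressed or set()
    out = []
    for el in elements:
        for g in genes:
            if g.chrom != el.chrom:
                continue
            if g.start < el.end + window and el.start - window < g.end:
                if g.end <= el.start:
                    dist = el.start - g.end
                elif el.end <= g.start:
                    dist = g.start - el.end
                else:
                    dist = 0
                out.append(ProximityRecord(g.id, el.id, dist,
                                           el.id in expressed))
    out.sort(key=lambda r: (r.element_id, r.gene_id))
    return out


def categorize_expression(rpkm_mean: float) -> str:
    """[0,1) -> not, [1,10) -> low, [10,100) -> medium, [100,inf) -> high."""
    if rpkm_mean < 0:
        raise ValueError("RPKM must be non-negative")
    if rpkm_mean < _BOUNDS[0]:
        return "not"
    if rpkm_mean < _BOUNDS[1]:
        return "low"
    if rpkm_mean < _BOUNDS[2]:
        return "medium"
    return "high"


def category_table(records: list[ProximityRecord],
                   gene_rpkm: dict[str, float]) -> pd.DataFrame:
    """4x2 table of gene counts: expression category x element group.

    A gene near both an expressed and a not-expressed element counts in
    the near-expressed group (activity dominates); each gene counts once.
    """
    group: dict[str, bool] = {}
    for r in records:
        group[r.gene_id] = group.get(r.gene_id, False) or r.element_expressed
    table = pd.DataFrame(0, index=list(CATEGORIES),
                         columns=["near_expressed", "near_not_expressed"])
    for gid, near_expr in group.items():
        cat = categorize_expression(gene_rpkm.get(gid, 0.0))
        col = "near_expressed" if near_expr else "near_not_expressed"
        table.loc[cat, col] += 1
    return table


def compare_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category 2x2 Fisher's exact tests (two-sided) with BH-FDR.

    Each category is tested in-category vs not, near-expressed group vs
    near-not-expressed group."""
    if (table.sum(axis=0) == 0).any():
        raise ValueError("both element groups must contain genes")
    totals = table.sum(axis=0)
    rows = []
    for cat in table.index:
        a = int(table.loc[cat, "near_expressed"])
        b = int(table.loc[cat, "near_not_expressed"])
        c = int(totals["near_expressed"] - a)
        d = int(totals["near_not_expressed"] - b)
        _odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"category": cat, "near_expressed": a,
                     "near_not_expressed": b, "p_value": p})
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < 0.05
    return out


def go_enrichment(selection: set[str], background: set[str],
                  annotations: dict[str, set[str]],
                  fdr_threshold: float = 0.05) -> list[EnrichmentResult]:
    """GO over-representation of a gene selection against a background.

    One-sided (greater) Fisher's exact test per term with at least one
    selected gene; genes without annotation are excluded from the term
    tables; BH-FDR over the tested terms.
    """
    if not selection:
        raise ValueError("selection must be non-empty")
    if not selection <= background:
        raise ValueError("selection must be a subset of the background")
    annotated_bg = {g for g in background if annotations.get(g)}
    annotated_sel = {g for g in selection if annotations.get(g)}
    term_bg: dict[str, int] = {}
    term_sel: dict[str, int] = {}
    for g in annotated_bg:
        for t in annotations[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in annotated_sel:
                term_sel[t] = term_sel.get(t, 0) + 1
    N, n = len(annotated_bg), len(annotated_sel)
    results = []
    for term in sorted(term_sel):
        k, K = term_sel[term], term_bg[term]
        _odds, p = stats.fisher_exact(
            [[k, n - k], [K - k, N - n - (K - k)]], alternative="greater")
        results.append(EnrichmentResult(term, k, K, n, N, p, float("nan"),
                                        False))
    if results:
        fdr = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            r.enriched = q < fdr_threshold
    return results
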