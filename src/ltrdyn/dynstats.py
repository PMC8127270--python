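"""Per-lineage summaries and trend statistics.

Lineage composition tables (counts and round-half-up percentages), one-way
ANOVA with Tukey HSD and a compact letter display across lineages, ordinary
least-squares regressions among insertion age, genomic abundance and
expression, and the per-treatment slope table of expression against age
and against abundance (Copia elements only for the expression
correlations, Gypsy expression being too low to regress on).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("C24", "S24", "C48", "S48")


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    tukey_pvalues: dict[tuple[str, str], float]
    letters: dict[str, str]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float | None
    n: int


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def lineage_summary(annotations: list[tuple[str, str]]) -> pd.DataFrame:
    """Counts and percentages per (superfamily, lineage).

    `annotations` holds (superfamily, lineage) pairs, one per element.
    Percentages are reported both of the superfamily total and of the
    grand total, rounded half-up to 2 decimals.
    """
    df = pd.DataFrame(annotations, columns=["superfamily", "lineage"])
    grand = len(df)
    rows = []
    for sf, sub in df.groupby("superfamily", sort=True):
        sf_total = len(sub)
        for lin, linsub in sub.groupby("lineage", sort=True):
            rows.append({
                "superfamily": sf, "lineage": lin, "count": len(linsub),
                "pct_of_superfamily": _pct(len(linsub), sf_total),
                "pct_of_total": _pct(len(linsub), grand),
            })
    out = pd.DataFrame(rows)
    return out


def superfamily_summary(annotations: list[tuple[str, str]]) -> pd.DataFrame:
    df = pd.DataFrame(annotations, columns=["superfamily", "lineage"])
    grand = len(df)
    rows = [{"superfamily": sf, "count": len(sub),
             "pct_of_total": _pct(len(sub), grand)}
            for sf, sub in df.groupby("superfamily", sort=True)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey letters
# ---------------------------------------------------------------------------

def anova_tukey(values_by_group: dict[str, list[float]],
                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey HSD (Tukey-Kramer for unequal n) and a
    compact letter display.

    Groups sharing a letter are not significantly different at `alpha`.
    With zero variance everywhere and equal means the F statistic is
    undefined and the result is reported as non-significant.
    """
    names = list(values_by_group)
    if len(names) < 2 or any(len(v) < 2 for v in values_by_group.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    means = {g: float(a.mean()) for g, a in zip(names, arrays)}

    pooled_var = np.concatenate([a - a.mean() for a in arrays]).var()
    if pooled_var == 0:
        # no within-group variance: F is 0/0 when means are equal too
        if len({round(m, 12) for m in means.values()}) == 1:
            pairs = {(a, b): 1.0 for i, a in enumerate(names)
                     for b in names[i + 1:]}
            return AnovaResult(float("nan"), 1.0, means, pairs,
                               {g: "a" for g in names})

    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairs: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pairs[(a, names[j])] = float(hsd.pvalue[i, j])
    letters = compact_letter_display(names, means, pairs, alpha)
    return AnovaResult(float(f_stat), float(p), means, pairs, letters)


def compact_letter_display(names: list[str], means: dict[str, float],
                           pairwise_p: dict[tuple[str, str], float],
                           alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb construction of the compact letter display from
    the pairwise non-significance graph; letter order follows descending
    group means."""
    def pval(a: str, b: str) -> float:
        return pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))

    order = sorted(names, key=lambda g: (-means[g], g))
    sets: list[set[str]] = [set(order)]
    sig_pairs = sorted(
        [(a, b) for (a, b), p in pairwise_p.items() if p < alpha],
        key=lambda ab: (pval(*ab), ab))
    for a, b in sig_pairs:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: (min(order.index(g) for g in s), -len(s)))
    letters = {g: "" for g in names}
    for k, s in enumerate(sets):
        ch = chr(ord("a") + k)
        for g in order:
            if g in s:
                letters[g] += ch
    return letters


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def regress(x: list[float] | np.ndarray, y: list[float] | np.ndarray
            ) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson r and two-sided p.

    A p-value requires n >= 3; constant x is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if len(x) >= 3 else None
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue), p, len(x))


def slope_table(joined: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment regression slopes of expression against insertion age
    and against genomic abundance, mirroring a 4-treatment slope table.

    `joined` needs columns: superfamily, age_years, coverage, and
    rpkm_C24/rpkm_S24/rpkm_C48/rpkm_S48.  Only Copia elements enter the
    expression correlations.
    """
    for t in TREATMENTS:
        if f"rpkm_{t}" not in joined.columns:
            raise ValueError(f"missing treatment column rpkm_{t}")
    copia = joined[joined["superfamily"] == "Copia"]
    rows = []
    for kind, xcol in (("expression_vs_insertion_time", "age_years"),
                       ("expression_vs_genome_abundance", "coverage")):
        for t in TREATMENTS:
            sub = copia[[xcol, f"rpkm_{t}"]].dropna()
            if len(sub) < 2 or np.ptp(sub[xcol].to_numpy()) == 0:
                raise ValueError(f"treatment {t}: not enough data to regress")
            r = regress(sub[xcol], sub[f"rpkm_{t}"])
            rows.append({"correlation": kind, "treatment": t,
                         "slope": r.slope, "r": r.r, "p_value": r.p_value,
                         "n": r.n})
    return pd.DataFrame(rows)
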