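"""Read-to-element assignment, genomic abundance, RPKM and DE calling.

Reads are assigned to reference sequences when they align at >= 90%
identity over >= 90% of the read length (both thresholds configurable).
The alignment contract is full-query infix alignment: the whole read must
fit inside the reference, and identity is computed over the full read
length, so partially overhanging reads fail through inflated edit
distance.  Genomic abundance is average coverage (aligned bases / element
length); expression is RPKM; differential expression between conditions
uses a negative-binomial exact test conditioned on the pooled count with a
common method-of-moments dispersion, an approximation of the pairwise
exact test of the edgeR family of methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SequenceRecord
from .simulate import LibraryDesign, reverse_complement


@dataclass
class ReadAssignment:
    read_id: str
    elements: list[str]          # all references passing the thresholds
    primary: str                 # best-scoring passing reference
    identity: float              # percent, of the primary alignment
    aligned_fraction: float
    aligned_bases: int
    unique: bool


@dataclass
class AbundanceRecord:
    element_id: str
    coverage: float              # aligned bases / element length
    coverage_per_million: float  # additionally normalised per 1e6 reads


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame         # element x library, integers
    rpkm: pd.DataFrame
    library_totals: pd.Series    # mapped-read counts per library
    unique_fraction: pd.Series


@dataclass
class DEResult:
    element_id: str
    log2_fold_change: float
    fold_change: float
    p_value: float
    fdr: float = float("nan")
    status: str = "ns"           # up | down | ns


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------

class ReadMapper:
    """K-mer prefilter + edlib infix alignment against a reference set."""

    def __init__(self, references: list[SequenceRecord],
                 min_identity: float = 0.9, min_len_frac: float = 0.9,
                 kmer: int = 13, seed: int = 0):
        if not references:
            raise ValueError("reference collection must be non-empty")
        self.refs = {r.id: r.residues for r in references}
        self.min_identity = min_identity
        self.min_len_frac = min_len_frac
        self.k = kmer
        # tie-break order: reference ids in a seeded shuffle
        rng = np.random.default_rng(seed)
        ids = sorted(self.refs)
        self.tie_order = {rid: i for i, rid in
                          enumerate(np.array(ids)[rng.permutation(len(ids))])}
        self.index: dict[str, set[str]] = {}
        for rid, seq in self.refs.items():
            for i in range(0, len(seq) - kmer + 1):
                self.index.setdefault(seq[i:i + kmer], set()).add(rid)

    def _candidates(self, seq: str) -> set[str]:
        cands: set[str] = set()
        for i in range(0, max(len(seq) - self.k, 0) + 1, self.k):
            cands |= self.index.get(seq[i:i + self.k], set())
        return cands

    def map_read(self, read: SequenceRecord) -> ReadAssignment | None:
        L = len(read.residues)
        max_edits = int(L * (1.0 - self.min_identity))
        rc = reverse_complement(read.residues)
        hits: dict[str, int] = {}
        for seq in (read.residues, rc):
            for rid in self._candidates(seq):
                res = edlib.align(seq, self.refs[rid], mode="HW",
                                  task="distance", k=max_edits)
                d = res["editDistance"]
                if d >= 0 and (rid not in hits or d < hits[rid]):
                    hits[rid] = d
        if not hits:
            return None
        best = min(hits.values())
        primary = min((rid for rid, d in hits.items() if d == best),
                      key=lambda rid: self.tie_order[rid])
        return ReadAssignment(
            read_id=read.id, elements=sorted(hits), primary=primary,
            identity=100.0 * (1 - best / L), aligned_fraction=1.0,
            aligned_bases=L, unique=len(hits) == 1)


def map_reads(reads: list[SequenceRecord], references: list[SequenceRecord],
              min_identity: float = 0.9, min_len_frac: float = 0.9,
              seed: int = 0) -> list[ReadAssignment]:
    """Assign each read to the references it matches; unmapped reads are
    simply absent from the result (callers count them by difference)."""
    mapper = ReadMapper(references, min_identity, min_len_frac, seed=seed)
    out = []
    for read in reads:
        a = mapper.map_read(read)
        if a is not None:
            out.append(a)
    return out


def average_coverage(assignments: list[ReadAssignment],
                     element_lengths: dict[str, int],
                     n_reads_total: int | None = None
                     ) -> dict[str, AbundanceRecord]:
    """Aligned bases of primary assignments per element / element length."""
    bases: dict[str, int] = {eid: 0 for eid in element_lengths}
    for a in assignments:
        if a.primary in bases:
            bases[a.primary] += a.aligned_bases
    n_reads = n_reads_total if n_reads_total is not None else len(assignments)
    out = {}
    for eid, length in element_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {eid}")
        cov = bases[eid] / length
        out[eid] = AbundanceRecord(eid, cov,
                                   cov * 1e6 / n_reads if n_reads else 0.0)
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def rpkm(counts: pd.DataFrame, element_lengths: dict[str, int],
         library_totals: pd.Series | dict[str, int]) -> pd.DataFrame:
    """rpkm[e, l] = counts[e, l] * 1e9 / (totals[l] * length[e])."""
    totals = pd.Series(library_totals).reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    lengths = pd.Series(element_lengths).reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("element lengths must be positive")
    return counts.mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def expression_matrix(assignments_by_library: dict[str, list[ReadAssignment]],
                      element_lengths: dict[str, int],
                      library_totals: dict[str, int] | None = None
                      ) -> ExpressionMatrix:
    """Counts (primary assignments), RPKM and unique fractions per library.

    library_totals defaults to the number of mapped reads per library; pass
    the full library sizes to normalise by total sequenced reads instead.
    """
    libs = list(assignments_by_library)
    counts = pd.DataFrame(0, index=list(element_lengths), columns=libs)
    uniq = {}
    for lib, assignments in assignments_by_library.items():
        for a in assignments:
            if a.primary in counts.index:
                counts.loc[a.primary, lib] += 1
        uniq[lib] = (np.mean([a.unique for a in assignments])
                     if assignments else 1.0)
    totals = pd.Series(library_totals if library_totals is not None
                       else {lib: len(a) for lib, a in
                             assignments_by_library.items()})
    return ExpressionMatrix(counts, rpkm(counts, element_lengths, totals),
                            totals, pd.Series(uniq))


def call_expressed(rpkm_df: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Elements with RPKM strictly greater than `threshold` in at least one
    library."""
    mask = (rpkm_df > threshold).any(axis=1)
    return set(rpkm_df.index[mask])


def condition_sets(rpkm_df: pd.DataFrame, design: list[LibraryDesign],
                   threshold: float = 1.0
                   ) -> tuple[dict[str, set[str]], pd.DataFrame,
                              dict[tuple[bool, bool, bool, bool], int]]:
    """Per-treatment expressed sets and their Venn intersection counts.

    Returns ({treatment: expressed set}, membership table, counts keyed by
    the (C24, S24, C48, S48) membership tuple).
    """
    treatments = ("C24", "S24", "C48", "S48")
    by_treatment: dict[str, list[str]] = {t: [] for t in treatments}
    for lib in design:
        if lib.name in rpkm_df.columns:
            by_treatment[lib.treatment].append(lib.name)
    sets = {t: (call_expressed(rpkm_df[cols], threshold) if cols else set())
            for t, cols in by_treatment.items()}
    member = pd.DataFrame(
        {t: [e in sets[t] for e in rpkm_df.index] for t in treatments},
        index=rpkm_df.index)
    counts: dict[tuple[bool, bool, bool, bool], int] = {}
    expressed_any = member.any(axis=1)
    for key, group in member[expressed_any].groupby(list(treatments)):
        counts[tuple(key)] = len(group)
    return sets, member, counts


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _moment_dispersion(scaled: np.ndarray, groups: list[np.ndarray]) -> float:
    """Common NB dispersion by the method of moments: a ratio-of-sums
    estimate of (var - mean) / mean^2 pooled over elements and groups."""
    num = den = 0.0
    for idx in groups:
        sub = scaled[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m ** 2))
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _nb_exact_pvalue(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact test of equal means given the pooled count sa+sb.

    Group sums are NB (or Poisson when phi == 0); conditioning on the total
    gives a discrete distribution over the split; the p-value is the
    probability mass of all splits no more likely than the observed one.
    """
    s = sa + sb
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(a, s, na / (na + nb))
    else:
        mu = s / (na + nb)
        size_a, size_b = na / phi, nb / phi
        pa = size_a / (size_a + na * mu)
        pb = size_b / (size_b + nb * mu)
        logp = (stats.nbinom.logpmf(a, size_a, pa)
                + stats.nbinom.logpmf(s - a, size_b, pb))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(np.sum(p[p <= p[sa] * (1 + 1e-10)]))


def differential_expression(counts: pd.DataFrame, design: list[LibraryDesign],
                            timepoint: int, fc_threshold: float = 2.0,
                            fdr_threshold: float = 0.05,
                            library_totals: pd.Series | None = None
                            ) -> list[DEResult]:
    """Salt-vs-control DE calls at one timepoint.

    Counts are normalised by library totals to a common size, the NB exact
    test is applied per element, and BH-FDR is computed across tested
    elements.  An element is up/down only if its fold change exceeds
    fc_threshold (in either direction) AND FDR < fdr_threshold.
    """
    ctrl = [d.name for d in design
            if d.timepoint == timepoint and d.condition == "control"]
    salt = [d.name for d in design
            if d.timepoint == timepoint and d.condition == "salt"]
    if len(ctrl) < 2 or len(salt) < 2:
        raise ValueError("need >= 2 replicates per condition")
    cols = ctrl + salt
    sub = counts[cols].to_numpy(dtype=float)
    totals = (library_totals.reindex(cols).to_numpy(dtype=float)
              if library_totals is not None else sub.sum(axis=0))
    if (totals <= 0).any():
        raise ValueError("a condition has all-zero library totals")
    common = totals.mean()
    scaled = sub * (common / totals)

    ia = np.arange(len(ctrl))
    ib = np.arange(len(ctrl), len(cols))
    phi = _moment_dispersion(scaled, [ia, ib])

    sa = np.rint(scaled[:, ia].sum(axis=1)).astype(int)
    sb = np.rint(scaled[:, ib].sum(axis=1)).astype(int)
    mean_a = scaled[:, ia].mean(axis=1)
    mean_b = scaled[:, ib].mean(axis=1)

    results: list[DEResult] = []
    pvals = []
    for i, eid in enumerate(counts.index):
        p = _nb_exact_pvalue(int(sa[i]), int(sb[i]), len(ia), len(ib), phi)
        eps = 1e-8
        fc = (mean_b[i] + eps) / (mean_a[i] + eps)
        results.append(DEResult(eid, float(np.log2(fc)), float(fc), p))
        pvals.append(p)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        if q < fdr_threshold and (r.fold_change > fc_threshold
                                  or r.fold_change < 1.0 / fc_threshold):
            r.status = "up" if r.fold_change > 1 else "down"
    return results
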