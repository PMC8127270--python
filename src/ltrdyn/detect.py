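"""Structural detection of full-length LTR retroelements.

A full-length element is a pair of similar direct repeats (the LTRs) whose
lengths, overall span, alignment identity and flanking target-site
duplication satisfy the detection parameters.  The detector runs in three
stages: exact k-mer seed pairs, merged into maximal exact matches; chaining
and ungapped X-drop extension into candidate LTR pairs; and filtering
(length/identity bounds, overlap resolution, TSD search, nesting).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import edlib

from .io import LTRElement, PipelineConfig, SequenceRecord
from .dating import align_ltrs, alignment_identity


@dataclass
class DetectionParams:
    """Bounds of the structural search, defaults as published."""

    min_ltr_len: int = 100
    max_ltr_len: int = 6000
    min_elem_len: int = 1500
    max_elem_len: int = 25000
    tsd_len: int = 5
    min_similarity: float = 85.0
    vicinity: int = 10
    seed_kmer: int = 20
    require_tsd: bool = True
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_ltr_len < self.max_ltr_len):
            raise ValueError("need 0 < min_ltr_len < max_ltr_len")
        if not (0 < self.min_elem_len < self.max_elem_len):
            raise ValueError("need 0 < min_elem_len < max_elem_len")
        if not (0 < self.min_similarity <= 100):
            raise ValueError("min_similarity must be in (0, 100]")

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "DetectionParams":
        return cls(cfg.min_ltr_len, cfg.max_ltr_len, cfg.min_elem_len,
                   cfg.max_elem_len, cfg.tsd_len, cfg.min_similarity,
                   cfg.vicinity, cfg.seed_kmer, cfg.require_tsd)


@dataclass
class Cluster:
    representative: str
    members: list[str]
    identities: dict[str, float]


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def find_seed_repeats(seq: str, k: int, max_span: int
                      ) -> list[tuple[int, int, int]]:
    """All maximal exact direct-repeat pairs of length >= k whose start
    separation is <= max_span, as (pos1, pos2, length) with pos1 < pos2.

    Found via a k-mer index: co-diagonal k-mer matches are merged into
    maximal runs (one maximal pair per offset).  Reverse-complement pairs
    are not considered.
    """
    if k < 8:
        raise ValueError("seed k-mer must be >= 8")
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)

    by_diag: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                p1, p2 = positions[a], positions[b]
                if p2 - p1 <= max_span:
                    by_diag[p2 - p1].append(p1)

    out: list[tuple[int, int, int]] = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = starts[0]
        run_end = starts[0] + k
        for p in starts[1:]:
            if p <= run_end - k + 1:
                run_end = max(run_end, p + k)
            else:
                out.append((run_start, run_start + diag, run_end - run_start))
                run_start, run_end = p, p + k
        out.append((run_start, run_start + diag, run_end - run_start))
    out.sort()
    return out


def find_seed_repeats_bruteforce(seq: str, k: int, max_span: int
                                 ) -> list[tuple[int, int, int]]:
    """Quadratic reference implementation: scan every diagonal for maximal
    match runs.  For cross-checking the indexed finder on small inputs."""
    n = len(seq)
    out = []
    for diag in range(1, min(max_span, n - 1) + 1):
        run = 0
        for i in range(n - diag):
            if seq[i] == seq[i + diag]:
                run += 1
            else:
                if run >= k:
                    out.append((i - run, i - run + diag, run))
                run = 0
        if run >= k:
            start = n - diag - run
            out.append((start, start + diag, run))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Extension and candidate assembly
# ---------------------------------------------------------------------------

def _xdrop_extend(seq: str, i: int, j: int, step: int,
                  match: int = 1, mismatch: int = -2, xdrop: int = 12
                  ) -> int:
    """Ungapped X-drop extension comparing seq[i], seq[j] and stepping by
    `step`; returns the number of columns of the best-scoring extension."""
    best = 0
    score = 0
    best_len = 0
    length = 0
    n = len(seq)
    while 0 <= i < n and 0 <= j < n:
        score += match if seq[i] == seq[j] else mismatch
        length += 1
        if score > best:
            best, best_len = score, length
        if score < best - xdrop:
            break
        i += step
        j += step
    return best_len


def _chain_seeds(seeds: list[tuple[int, int, int]], band: int = 20,
                 max_gap: int = 800) -> list[list[tuple[int, int, int]]]:
    """Group co-linear seeds whose diagonals differ by <= band and whose
    spans are within max_gap of each other."""
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    chains: list[list[tuple[int, int, int]]] = []
    for s in seeds:
        placed = False
        d = s[1] - s[0]
        for chain in reversed(chains):
            last = chain[-1]
            ld = last[1] - last[0]
            if abs(d - ld) <= band and 0 <= s[0] - (last[0] + last[2]) <= max_gap:
                chain.append(s)
                placed = True
                break
            if abs(d - ld) > band and d - ld > band:
                break
        if not placed:
            chains.append([s])
    return chains


def detect_full_length(genome: list[SequenceRecord],
                       params: DetectionParams | None = None
                       ) -> list[LTRElement]:
    """Detect candidate full-length elements in a genome.

    Candidates violating any length or identity bound are never reported.
    Overlapping candidates are resolved by keeping the higher-similarity
    one.  The TSD search may shift boundaries by at most `vicinity` bp;
    candidates without a TSD are kept but flagged (tsd=None).  Elements
    lying wholly inside another element's internal region are flagged
    nested.  With require_tsd (the default), TSD-less and nested candidates
    are excluded from the returned list; set require_tsd=False to keep them.
    """
    params = params or DetectionParams()
    candidates: list[LTRElement] = []
    for contig in genome:
        candidates.extend(_detect_in_contig(contig, params))

    kept: list[LTRElement] = []
    for cand in sorted(candidates, key=lambda c: (-c.similarity, c.chrom, c.start)):
        if any(k.chrom == cand.chrom and k.start < cand.end and cand.start < k.end
               for k in kept):
            continue
        kept.append(cand)

    # nested: element interval wholly inside another's internal region
    for cand in kept:
        for other in kept:
            if other is cand or other.chrom != cand.chrom:
                continue
            if other.ltr5_end <= cand.start and cand.end <= other.ltr3_start:
                cand.nested = True
                break

    kept.sort(key=lambda c: (c.chrom, c.start))
    for i, cand in enumerate(kept):
        cand.id = f"LTRRE{i:04d}"
    if params.require_tsd:
        kept = [c for c in kept if c.tsd is not None and not c.nested]
    return kept


def _detect_in_contig(contig: SequenceRecord, params: DetectionParams
                      ) -> list[LTRElement]:
    seq = contig.residues
    seeds = find_seed_repeats(seq, params.seed_kmer, params.max_elem_len)
    # a valid seed pair cannot overlap itself and must leave room for an
    # element span of at least min_elem_len after extension
    seeds = [s for s in seeds if s[1] >= s[0] + s[2]]
    out: list[LTRElement] = []
    for chain in _chain_seeds(seeds):
        s5 = min(s[0] for s in chain)
        e5 = max(s[0] + s[2] for s in chain)
        s3 = min(s[1] for s in chain)
        e3 = max(s[1] + s[2] for s in chain)
        if s3 < e5:  # the two repeat copies must not overlap
            continue
        left = _xdrop_extend(seq, s5 - 1, s3 - 1, -1)
        right = _xdrop_extend(seq, e5, e3, +1)
        s5, s3 = s5 - left, s3 - left
        e5, e3 = e5 + right, e3 + right
        len5, len3 = e5 - s5, e3 - s3
        elem_len = e3 - s5
        if not (params.min_ltr_len <= len5 <= params.max_ltr_len):
            continue
        if not (params.min_ltr_len <= len3 <= params.max_ltr_len):
            continue
        if not (params.min_elem_len <= elem_len <= params.max_elem_len):
            continue
        ltr5_seq, ltr3_seq = seq[s5:e5], seq[s3:e3]
        if max(ltr5_seq.count("N") / len5, ltr3_seq.count("N") / len3) \
                > params.max_n_fraction:
            continue
        aln = align_ltrs(ltr5_seq, ltr3_seq)
        sim = alignment_identity(aln)
        if sim < params.min_similarity:
            continue
        cand = LTRElement(
            id="", chrom=contig.id, start=s5, end=e3,
            ltr5_start=s5, ltr5_end=e5, ltr3_start=s3, ltr3_end=e3,
            similarity=sim)
        tsd = find_tsd(seq, cand, params)
        if tsd is not None:
            cand.tsd = tsd
            # re-check bounds after the TSD boundary shift
            if not (params.min_elem_len <= cand.length <= params.max_elem_len):
                continue
        out.append(cand)
    return out


def find_tsd(seq: str, candidate: LTRElement, params: DetectionParams
             ) -> str | None:
    """Search for a tsd_len-mer duplicated immediately left of the element
    start and right of the element end, allowing boundary shifts of at most
    `vicinity` bp on each side.  On success the candidate's boundaries are
    updated in place.  Ties: smallest total shift, then leftmost start."""
    t, vic = params.tsd_len, params.vicinity
    start, end = candidate.start, candidate.end
    shifts = sorted(
        ((i, j) for i in range(-vic, vic + 1) for j in range(-vic, vic + 1)),
        key=lambda ij: (abs(ij[0]) + abs(ij[1]), ij[0], ij[1]))
    for i, j in shifts:
        s, e = start + i, end + j
        if s - t < 0 or e + t > len(seq):
            continue
        left = seq[s - t:s]
        right = seq[e:e + t]
        if left == right and "N" not in left:
            candidate.start = s
            candidate.end = e
            candidate.ltr5_start = s
            candidate.ltr3_end = e
            return left
    return None


# ---------------------------------------------------------------------------
# Redundancy clustering
# ---------------------------------------------------------------------------

def cluster_elements(element_seqs: list[SequenceRecord],
                     threshold: float = 90.0) -> list[Cluster]:
    """Greedy incremental clustering at a percent-identity threshold.

    Sequences are sorted by descending length (stable on id); each joins
    the first existing cluster whose representative aligns to it at
    >= threshold identity over at least 80% of the shorter sequence, else
    founds a new cluster.  Identity is computed from a full-query infix
    alignment of the shorter sequence against the longer, so the coverage
    condition is met by construction.
    """
    if not element_seqs:
        raise ValueError("need at least one sequence")
    ordered = sorted(element_seqs, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    reps: list[SequenceRecord] = []
    for rec in ordered:
        joined = False
        for cluster, rep in zip(clusters, reps):
            ident = _percent_identity(rec.residues, rep.residues)
            if ident >= threshold:
                cluster.members.append(rec.id)
                cluster.identities[rec.id] = ident
                joined = True
                break
        if not joined:
            clusters.append(Cluster(rec.id, [rec.id], {rec.id: 100.0}))
            reps.append(rec)
    return clusters


def _percent_identity(query: str, target: str) -> float:
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return 100.0 * (1.0 - d / len(query))
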