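"""Domain-based annotation of element internal regions.

Each reference protein domain (GAG, PR, INT, RT, RH) is locally aligned
against all six translation frames of the element's internal region.
Superfamily follows from the polyprotein domain order on the coding strand
(integrase upstream of reverse transcriptase = Copia, downstream = Gypsy),
lineage from the modal lineage label of the hits, and an element is
autonomous only when all five domains are present.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .simulate import load_domain_reference

DOMAINS = ("GAG", "PR", "INT", "RT", "RH")


@dataclass
class DomainReference:
    name: str
    domain: str
    superfamily: str
    lineage: str
    protein: str


@dataclass
class DomainHit:
    domain: str
    frame: int            # +1..+3, -1..-3
    start: int            # element-internal nt coordinates, half-open
    end: int
    identity: float       # percent over aligned columns
    score: float
    lineage: str
    superfamily: str


@dataclass
class ElementAnnotation:
    superfamily: str      # Copia | Gypsy | unknown
    lineage: str
    autonomous: bool
    domain_order: list[str]
    conflicting: bool = False  # hits disagreed on superfamily/lineage


def bundled_reference() -> list[DomainReference]:
    return [DomainReference(r["name"], r["domain"], r["superfamily"],
                            r["lineage"], r["protein"])
            for r in load_domain_reference()]


def parse_domain_fasta(path) -> list[DomainReference]:
    """User-supplied reference: protein FASTA with header syntax
    >NAME|DOMAIN|SUPERFAMILY|LINEAGE"""
    refs: list[DomainReference] = []
    header, chunks = None, []

    def flush():
        if header is None:
            return
        name, domain, superfamily, lineage = header.split("|")
        refs.append(DomainReference(name, domain, superfamily, lineage,
                                    "".join(chunks)))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header, chunks = line[1:].strip(), []
            elif line.strip():
                chunks.append(line.strip())
    flush()
    return refs


def translate_six_frames(dna: str) -> dict[int, str]:
    """Standard-code translation of frames +1..+3 and -1..-3; stop codons
    rendered as '*', trailing partial codons dropped."""
    if len(dna) < 3:
        raise ValueError("need at least one codon")
    dna = dna.upper()
    rc = str(Seq(dna).reverse_complement())
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        for strand, seq in ((+1, dna), (-1, rc)):
            sub = seq[f - 1:]
            sub = sub[:len(sub) - len(sub) % 3]
            out[strand * f] = str(Seq(sub).translate())
    return out


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def scan_domains(element_internal: str, refs: list[DomainReference] | None = None,
                 min_identity: float = 40.0, min_cov: float = 0.5
                 ) -> list[DomainHit]:
    """Best local protein hit per domain name across all frames and refs.

    A hit passes if its percent identity over aligned columns is
    >= min_identity and it covers >= min_cov of the reference protein.
    """
    refs = refs if refs is not None else bundled_reference()
    if not refs:
        raise ValueError("reference collection must be non-empty")
    if len(element_internal) < 3:
        return []
    frames = translate_six_frames(element_internal)
    aligner = _protein_aligner()
    best: dict[str, DomainHit] = {}
    L = len(element_internal)
    for ref in refs:
        for frame, prot in frames.items():
            if not prot:
                continue
            alns = aligner.align(ref.protein, prot)
            if len(alns) == 0:
                continue
            aln = alns[0]
            score = aln.score
            matches = cols = 0
            for (qs, qe), (ts, te) in zip(*aln.aligned):
                for q, t in zip(ref.protein[qs:qe], prot[ts:te]):
                    cols += 1
                    if q == t:
                        matches += 1
            if cols == 0:
                continue
            identity = 100.0 * matches / cols
            ref_cov = sum(qe - qs for qs, qe in aln.aligned[0]) / len(ref.protein)
            if identity < min_identity or ref_cov < min_cov:
                continue
            aa_start = aln.aligned[1][0][0]
            aa_end = aln.aligned[1][-1][1]
            off = abs(frame) - 1
            if frame > 0:
                nt_start, nt_end = off + 3 * aa_start, off + 3 * aa_end
            else:
                nt_start, nt_end = L - off - 3 * aa_end, L - off - 3 * aa_start
            hit = DomainHit(ref.domain, frame, nt_start, nt_end, identity,
                            float(score), ref.lineage, ref.superfamily)
            cur = best.get(ref.domain)
            if cur is None or hit.score > cur.score:
                best[ref.domain] = hit
    return sorted(best.values(), key=lambda h: h.start)


def classify_element(hits: list[DomainHit]) -> ElementAnnotation:
    """Superfamily, lineage and autonomy from a set of domain hits.

    Pure function of the hit set.  Superfamily by INT/RT order on the
    coding strand; if undecidable, majority of hit reference labels.
    Lineage is the modal lineage label, ties by summed score then
    alphabetically.  Autonomous iff all five domains hit.
    """
    if not hits:
        return ElementAnnotation("unknown", "unknown", False, [])
    present = {h.domain for h in hits}
    autonomous = all(d in present for d in DOMAINS)

    by_domain = {h.domain: h for h in hits}
    superfamily = None
    if "INT" in by_domain and "RT" in by_domain:
        neg = sum(1 for h in hits if h.frame < 0)
        minus_strand = neg > len(hits) / 2
        int_first = by_domain["INT"].start < by_domain["RT"].start
        if minus_strand:
            int_first = not int_first
        if by_domain["INT"].start != by_domain["RT"].start:
            superfamily = "Copia" if int_first else "Gypsy"
    if superfamily is None:
        counts = Counter(h.superfamily for h in hits)
        top = counts.most_common()
        if len(top) == 1 or top[0][1] > top[1][1]:
            superfamily = top[0][0]
        else:
            scores: dict[str, float] = defaultdict(float)
            for h in hits:
                scores[h.superfamily] += h.score
            superfamily = min(sorted(scores), key=lambda s: (-scores[s], s))

    lin_counts = Counter(h.lineage for h in hits)
    lin_scores: dict[str, float] = defaultdict(float)
    for h in hits:
        lin_scores[h.lineage] += h.score
    lineage = sorted(lin_counts,
                     key=lambda l: (-lin_counts[l], -lin_scores[l], l))[0]

    conflicting = (len({h.superfamily for h in hits}) > 1
                   or len(lin_counts) > 1)
    order = [h.domain for h in sorted(hits, key=lambda h: h.start)]
    neg = sum(1 for h in hits if h.frame < 0)
    if neg > len(hits) / 2:
        order = order[::-1]
    return ElementAnnotation(superfamily, lineage, autonomous, order,
                             conflicting)
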