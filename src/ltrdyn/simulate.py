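"""Synthetic genomes with planted full-length LTR retroelements.

The generator is the test-bed for every downstream stage: it plants paired
LTRs of controlled divergence (so dating can be checked against known ages),
5-bp target-site duplications, internal domain cassettes in lineage- and
superfamily-appropriate order (so annotation can be checked), decoy solo
LTRs and truncated copies (so detection specificity and unique-read
accounting can be stressed), gene models with GO terms, and DNA/RNA read
sets whose coverage and expression follow configured per-element values
with negative-binomial replicate noise.

Layout: planted full-length elements, solo-LTR decoys and genes go on one
contig ("chr1"); truncated and internal-fragment family copies go on a
separate repeat contig ("chr2") spaced so that same-family copies are never
within detection range of each other.  This keeps redundancy stress (read
mapping, clustering) orthogonal to structural detection.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel, SequenceRecord

DNA = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# synonymous codons per amino acid; reverse translation picks among them
# (randomised per element copy, so cassette DNA diverges between copies
# while the encoded protein stays identical)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "*": ["TAA", "TAG", "TGA"],
}

SUPERFAMILY_ORDER = {
    # polyprotein domain order on the coding strand
    "Copia": ["GAG", "PR", "INT", "RT", "RH"],
    "Gypsy": ["GAG", "PR", "RT", "RH", "INT"],
}
LINEAGE_SUPERFAMILY = {"Ale": "Copia", "Angela": "Copia",
                       "Tekay": "Gypsy", "CRM": "Gypsy"}
TREATMENTS = ("C24", "S24", "C48", "S48")


def load_domain_reference() -> list[dict]:
    """Bundled synthetic protein domain reference.

    Returns records with keys name/domain/superfamily/lineage/protein.
    The sequences are randomly generated stand-ins, not real TE proteins.
    """
    refs = []
    path = (importlib.resources.files("ltrdyn") / "data"
            / "synthetic_domain_reference.faa")
    name = None
    seq: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                refs.append(_ref_record(name, "".join(seq)))
            name, seq = line[1:], []
        elif line.strip():
            seq.append(line.strip())
    if name is not None:
        refs.append(_ref_record(name, "".join(seq)))
    return refs


def _ref_record(header: str, protein: str) -> dict:
    name, domain, superfamily, lineage = header.split("|")
    return {"name": name, "domain": domain, "superfamily": superfamily,
            "lineage": lineage, "protein": protein}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome; the defaults define the package's
    standard desk-scale study conditions."""

    genome_length: int = 1_500_000
    lineage_counts: dict[str, int] = field(
        default_factory=lambda: {"Ale": 8, "Angela": 4, "Tekay": 5, "CRM": 3})
    ltr_len_range: tuple[int, int] = (300, 800)
    internal_len_range: tuple[int, int] = (1600, 3200)
    tsd_len: int = 5
    # per-lineage mean insertion age (years); elements draw uniformly
    # in [0.3, 1.7] x mean so every lineage spans young and old copies
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"Ale": 4e6, "Angela": 8e6,
                                 "Tekay": 3e6, "CRM": 9e6})
    substitution_rate: float = 2.36e-9
    nonautonomous_fraction: float = 0.3
    n_solo_ltr: int = 6
    n_truncated: int = 4
    max_extra_copies: int = 2      # internal-fragment copies per element
    copy_divergence: float = 0.04  # divergence of decoy/fragment copies
    min_spacing: int = 1000
    n_genes: int = 60
    gene_len_range: tuple[int, int] = (600, 1500)
    go_pool_size: int = 30
    go_enriched_terms: int = 4     # terms preferentially given to genes
    #                                near expressed elements
    expressed_fraction: float = 0.3
    expressed_level_range: tuple[float, float] = (3.0, 20.0)
    n_de: int = 2                  # elements with a planted salt response
    de_fold_change: float = 4.0
    de_timepoint: int = 48
    dispersion: float = 0.1
    library_size: int = 1_000_000
    read_length: int = 100
    proximity_effect: float = 3.0  # RPKM inflation of genes near expressed
    #                                elements
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.tsd_len <= 0:
            raise ValueError("lengths must be positive")
        lo, hi = self.ltr_len_range
        ilo, ihi = self.internal_len_range
        if 2 * lo + ilo < 1500 or 2 * hi + ihi > 25000:
            raise ValueError(
                "planted element length (2xLTR + internal) must stay in [1500, 25000]")

    @classmethod
    def detection_scenario(cls, seed: int) -> "SyntheticGenomeSpec":
        """The standard structural-detection benchmark: a 100-kb genome
        carrying 20 planted full-length elements and 10 decoys (6 solo
        LTRs + 4 truncated copies), no genes.  Element size ranges are
        tightened so the scenario packs for every seed."""
        return cls(genome_length=100_000,
                   ltr_len_range=(200, 600),
                   internal_len_range=(1100, 2000),
                   n_genes=0, n_solo_ltr=6, n_truncated=4,
                   max_extra_copies=1, min_spacing=500, seed=seed)


@dataclass
class TruthRecord:
    """Ground truth for one planted full-length element."""

    id: str
    chrom: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    tsd: str
    lineage: str
    superfamily: str
    age_years: float
    autonomous: bool
    copy_number: int
    # per-treatment expression level on the RPKM scale
    expression: dict[str, float] = field(default_factory=dict)

    @property
    def expressed(self) -> bool:
        return any(v > 1.0 for v in self.expression.values())


@dataclass
class LibraryDesign:
    """One RNA-seq library of the 2x2x3 design."""

    condition: str   # control | salt
    timepoint: int   # 24 | 48 (days)
    replicate: int
    library_size: int = 1_000_000

    @property
    def name(self) -> str:
        return f"{'C' if self.condition == 'control' else 'S'}{self.timepoint}_{self.replicate}"

    @property
    def treatment(self) -> str:
        return f"{'C' if self.condition == 'control' else 'S'}{self.timepoint}"


def full_design(library_size: int = 50_000) -> list[LibraryDesign]:
    """The complete 2 conditions x 2 timepoints x 3 replicates design."""
    return [LibraryDesign(cond, tp, rep, library_size)
            for cond in ("control", "salt")
            for tp in (24, 48)
            for rep in (1, 2, 3)]


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(DNA, size=length))


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability `divergence`; transitions are
    twice as likely as transversions (so that both K2P terms are exercised)."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
    for i in hits:
        base = out[i]
        if base not in _TRANSITION:  # N or ambiguity codes left untouched
            continue
        u = rng.random()
        if u < 2 / 3:
            out[i] = _TRANSITION[base]
        else:
            out[i] = _TRANSVERSIONS[base][0 if u < 5 / 6 else 1]
    return "".join(out)


def mutate_ltr_pair(ancestral_ltr: str, age: float, rate: float,
                    seed: int | np.random.Generator) -> tuple[str, str]:
    """Derive a 5'/3' LTR pair from an ancestral LTR after `age` years.

    Each copy mutates independently with per-site substitution probability
    age x rate, so the expected pairwise divergence is 2 x rate x age.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    p = age * rate
    if p >= 0.75:
        raise ValueError(
            f"age x rate = {p:.3f} >= 0.75: substitution saturation, "
            "K2P dating is undefined in this regime")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return mutate_sequence(ancestral_ltr, p, rng), mutate_sequence(ancestral_ltr, p, rng)


def reverse_translate(protein: str,
                      rng: np.random.Generator | None = None) -> str:
    """DNA encoding a protein; with an rng, synonymous codons are drawn at
    random (distinct element copies then share protein but not DNA)."""
    if rng is None:
        return "".join(_CODONS[aa][0] for aa in protein)
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
                   for aa in protein)


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq))


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _build_element(lineage: str, age: float, spec: SyntheticGenomeSpec,
                   refs: list[dict], autonomous: bool,
                   rng: np.random.Generator) -> dict:
    """Compose one full-length element (sequence parts + metadata)."""
    superfamily = LINEAGE_SUPERFAMILY[lineage]
    ltr_len = int(rng.integers(*spec.ltr_len_range))
    ancestral = random_dna(ltr_len, rng)
    ltr5, ltr3 = mutate_ltr_pair(ancestral, age, spec.substitution_rate, rng)

    order = SUPERFAMILY_ORDER[superfamily]
    lineage_refs = {r["domain"]: r for r in refs if r["lineage"] == lineage}
    domains = list(order)
    if not autonomous:
        drop = rng.choice(len(domains), size=int(rng.integers(1, 3)), replace=False)
        domains = [d for i, d in enumerate(domains) if i not in set(drop)]
    cassettes = [reverse_translate(lineage_refs[d]["protein"], rng)
                 for d in domains]

    internal_target = int(rng.integers(*spec.internal_len_range))
    spacer_total = max(internal_target - sum(map(len, cassettes)), 20 * (len(cassettes) + 1))
    cuts = np.sort(rng.integers(0, spacer_total + 1, size=len(cassettes)))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [spacer_total]]))
    parts = [random_dna(int(spacer_lens[0]), rng)]
    for cassette, slen in zip(cassettes, spacer_lens[1:]):
        parts.append(cassette)
        parts.append(random_dna(int(slen), rng))
    internal = "".join(parts)
    # the internal region accumulates substitutions since insertion too
    internal = mutate_sequence(internal, age * spec.substitution_rate, rng)

    tsd = random_dna(spec.tsd_len, rng)
    return {
        "lineage": lineage, "superfamily": superfamily, "age": age,
        "autonomous": autonomous, "ltr5": ltr5, "ltr3": ltr3,
        "internal": internal, "tsd": tsd, "ancestral_ltr": ancestral,
        "seq": ltr5 + internal + ltr3,
    }


@dataclass
class SyntheticDataset:
    """Everything simulate_genome produced: the contigs, the planted truth,
    gene models with GO terms, and the planted per-treatment gene levels."""

    contigs: list[SequenceRecord]
    truth: list[TruthRecord]
    genes: list[GeneModel]
    gene_go: dict[str, set[str]]
    gene_levels: dict[str, dict[str, float]]

    @property
    def genome(self) -> list[SequenceRecord]:
        return self.contigs


def simulate_genome(spec: SyntheticGenomeSpec) -> SyntheticDataset:
    """Build the synthetic genome.

    chr1 holds the planted full-length elements, solo-LTR decoys and genes;
    chr2 holds truncated and internal-fragment family copies, spaced beyond
    detection range of their relatives.
    """
    rng = np.random.default_rng(spec.seed)
    refs = load_domain_reference()

    elements = []
    idx = 0
    for lineage, count in sorted(spec.lineage_counts.items()):
        if lineage not in LINEAGE_SUPERFAMILY:
            raise ValueError(f"unsupported lineage {lineage!r}")
        for _ in range(count):
            age = float(spec.age_mean[lineage] * rng.uniform(0.3, 1.7))
            autonomous = rng.random() >= spec.nonautonomous_fraction
            el = _build_element(lineage, age, spec, refs, autonomous, rng)
            el["id"] = f"RE{idx:03d}"
            el["copy_number"] = int(rng.integers(0, spec.max_extra_copies + 1))
            elements.append(el)
            idx += 1

    # solo-LTR decoys: independent LTR-sized sequences flanked by a TSD
    solos = []
    for i in range(spec.n_solo_ltr):
        ltr = random_dna(int(rng.integers(*spec.ltr_len_range)), rng)
        tsd = random_dna(spec.tsd_len, rng)
        solos.append({"id": f"solo{i:02d}", "seq": ltr, "tsd": tsd})

    genes = []
    for i in range(spec.n_genes):
        genes.append({"id": f"gene{i:03d}",
                      "seq": random_dna(int(rng.integers(*spec.gene_len_range)), rng),
                      "strand": "+" if rng.random() < 0.5 else "-"})

    # ------------------------------------------------------------------ chr1
    inserts = ([("element", el) for el in elements]
               + [("solo", s) for s in solos]
               + [("gene", g) for g in genes])
    perm = rng.permutation(len(inserts))
    inserts = [inserts[i] for i in perm]

    def insert_len(kind, obj):
        if kind == "element":
            return len(obj["seq"]) + 2 * spec.tsd_len
        if kind == "solo":
            return len(obj["seq"]) + 2 * spec.tsd_len
        return len(obj["seq"])

    total = sum(insert_len(k, o) for k, o in inserts)
    n_gaps = len(inserts) + 1
    slack = spec.genome_length - total - n_gaps * spec.min_spacing
    if slack < 0:
        raise ValueError(
            f"infeasible packing: {total} bp of inserts + spacing exceed "
            f"genome_length {spec.genome_length}")
    extra = rng.multinomial(slack, np.full(n_gaps, 1 / n_gaps))

    chunks: list[str] = []
    pos = 0
    truth: list[TruthRecord] = []
    gene_models: list[GeneModel] = []

    def emit(s: str) -> None:
        nonlocal pos
        chunks.append(s)
        pos += len(s)

    emit(random_dna(spec.min_spacing + int(extra[0]), rng))
    for gap_i, (kind, obj) in enumerate(inserts, start=1):
        if kind == "element":
            emit(obj["tsd"])
            start = pos
            l5, li, l3 = len(obj["ltr5"]), len(obj["internal"]), len(obj["ltr3"])
            emit(obj["seq"])
            end = pos
            emit(obj["tsd"])
            truth.append(TruthRecord(
                id=obj["id"], chrom="chr1", start=start, end=end,
                ltr5_start=start, ltr5_end=start + l5,
                ltr3_start=end - l3, ltr3_end=end,
                tsd=obj["tsd"], lineage=obj["lineage"],
                superfamily=obj["superfamily"], age_years=obj["age"],
                autonomous=obj["autonomous"], copy_number=obj["copy_number"]))
            obj["interval"] = (start, end)
        elif kind == "solo":
            emit(obj["tsd"])
            emit(obj["seq"])
            emit(obj["tsd"])
        else:
            start = pos
            emit(obj["seq"])
            gene_models.append(GeneModel(obj["id"], "chr1", start, pos, obj["strand"]))
        emit(random_dna(spec.min_spacing + int(extra[gap_i]), rng))
    chr1 = SequenceRecord("chr1", "".join(chunks))

    # ------------------------------------------------------------------ chr2
    # family copies: truncated copies (partial internal + <100 bp LTR stub,
    # so they can never satisfy the paired-LTR length bounds) and
    # internal-region fragments implementing the planted copy numbers
    copies: list[tuple[str, str]] = []  # (family id, sequence)
    trunc_sources = rng.choice(len(elements), size=min(spec.n_truncated, len(elements)),
                               replace=False)
    for i in trunc_sources:
        el = elements[i]
        keep = int(len(el["internal"]) * rng.uniform(0.3, 0.7))
        stub = el["ltr3"][:80]
        seq = mutate_sequence(el["internal"][-keep:] + stub,
                              spec.copy_divergence, rng)
        copies.append((el["id"], seq))
    for el in elements:
        for _ in range(el["copy_number"]):
            frag_len = min(len(el["internal"]), int(rng.integers(800, 1600)))
            off = int(rng.integers(0, len(el["internal"]) - frag_len + 1))
            seq = mutate_sequence(el["internal"][off:off + frag_len],
                                  spec.copy_divergence, rng)
            copies.append((el["id"], seq))

    contigs = [chr1]
    if copies:
        # round-robin interleave by family, separated by spacers long enough
        # that same-family copies never fall within one detection span
        spacer = 26_000
        perm2 = rng.permutation(len(copies))
        chunks2 = [random_dna(spec.min_spacing, rng)]
        last_pos_by_family: dict[str, int] = {}
        pos2 = spec.min_spacing
        for i in perm2:
            fam, seq = copies[i]
            if fam in last_pos_by_family and pos2 - last_pos_by_family[fam] < spacer:
                pad = spacer - (pos2 - last_pos_by_family[fam])
                chunks2.append(random_dna(pad, rng))
                pos2 += pad
            last_pos_by_family[fam] = pos2 + len(seq)
            chunks2.append(seq)
            pos2 += len(seq)
            chunks2.append(random_dna(spec.min_spacing, rng))
            pos2 += spec.min_spacing
        contigs.append(SequenceRecord("chr2", "".join(chunks2)))

    # ------------------------------------------------------- expression plan
    n_expr = int(round(spec.expressed_fraction * len(truth)))
    ages = np.array([t.age_years for t in truth]) if truth else np.array([1.0])
    # younger elements are more likely to be transcribed
    w = np.exp(-ages / max(ages.mean(), 1.0))
    w /= w.sum()
    expr_idx = (rng.choice(len(truth), size=n_expr, replace=False, p=w)
                if truth else np.array([], dtype=int))
    for t in truth:
        t.expression = {tr: 0.0 for tr in TREATMENTS}
    de_pool = list(expr_idx)
    de_idx = (set(rng.choice(de_pool, size=min(spec.n_de, len(de_pool)),
                             replace=False).tolist()) if de_pool else set())
    for i in expr_idx:
        t = truth[i]
        base = float(rng.uniform(*spec.expressed_level_range))
        # expression decays with insertion age: old copies are silenced
        base *= float(np.exp(-t.age_years / (2 * ages.mean())))
        base = max(base, 1.5)
        for tr in TREATMENTS:
            t.expression[tr] = base
        if i in de_idx:
            t.expression[f"S{spec.de_timepoint}"] = base * spec.de_fold_change

    # gene expression: genes near expressed elements get inflated levels
    go_pool = [f"GO:{7000000 + k}" for k in range(spec.go_pool_size)]
    enriched_terms = go_pool[:spec.go_enriched_terms]
    near_expressed: set[str] = set()
    for g in gene_models:
        for t in truth:
            if t.expressed and g.chrom == t.chrom and \
                    g.start < t.end + 50_000 and t.start - 50_000 < g.end:
                near_expressed.add(g.id)
                break
    gene_go: dict[str, set[str]] = {}
    gene_levels: dict[str, dict[str, float]] = {}
    for g in gene_models:
        lvl = float(rng.lognormal(mean=1.0, sigma=1.5))
        if g.id in near_expressed:
            lvl *= spec.proximity_effect
            n_terms = int(rng.integers(2, 5))
            terms = set(rng.choice(enriched_terms, size=min(2, n_terms)).tolist())
            terms |= set(rng.choice(go_pool, size=n_terms - len(terms) + 1).tolist())
        else:
            n_terms = int(rng.integers(1, 4))
            terms = set(rng.choice(go_pool[spec.go_enriched_terms:],
                                   size=n_terms).tolist())
        gene_go[g.id] = terms
        g.go_terms = set(terms)
        gene_levels[g.id] = {tr: lvl for tr in TREATMENTS}
    return SyntheticDataset(contigs, truth, gene_models, gene_go, gene_levels)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_dna_reads(genome: list[SequenceRecord], fold_coverage: float,
                       read_length: int, error_rate: float,
                       seed: int) -> list[SequenceRecord]:
    """Uniform whole-genome shotgun reads from both strands.

    Read count = round(fold_coverage x genome_length / read_length);
    substitution errors at `error_rate` per base.
    """
    rng = np.random.default_rng(seed)
    glen = sum(len(c) for c in genome)
    if read_length > glen:
        raise ValueError("read_length exceeds genome length")
    n_reads = int(round(fold_coverage * glen / read_length))
    # contigs weighted by the number of valid start positions
    weights = np.array([max(len(c) - read_length + 1, 0) for c in genome], float)
    if weights.sum() == 0:
        raise ValueError("no contig long enough for one read")
    weights /= weights.sum()
    contig_idx = rng.choice(len(genome), size=n_reads, p=weights)
    reads = []
    for i in range(n_reads):
        ci = int(contig_idx[i])
        s = int(rng.integers(0, len(genome[ci]) - read_length + 1))
        seq = genome[ci].residues[s:s + read_length]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        if error_rate > 0:
            seq = mutate_sequence(seq, error_rate, rng)
        reads.append(SequenceRecord(f"dna_{i}", seq))
    return reads


def simulate_rna_counts(features: list[tuple[str, int, dict[str, float]]],
                        design: list[LibraryDesign], dispersion: float,
                        seed: int):
    """Negative-binomial counts per feature x library.

    `features` holds (id, length bp, per-treatment level on the RPKM scale).
    Expected count = level x (length/1e3) x (library_size/1e6), so the RPKM
    recomputed from a library of exactly `library_size` mapped reads equals
    the planted level in expectation.
    """
    import pandas as pd

    if len(design) != 12:
        warnings.warn(f"design has {len(design)} libraries, not the full 12",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    names = [d.name for d in design]
    mat = np.zeros((len(features), len(design)), dtype=int)
    for j, lib in enumerate(design):
        for i, (fid, length, levels) in enumerate(features):
            level = levels.get(lib.treatment, 0.0)
            mu = level * (length / 1e3) * (lib.library_size / 1e6)
            if mu <= 0:
                continue
            if dispersion > 0:
                n = 1.0 / dispersion
                p = n / (n + mu)
                mat[i, j] = rng.negative_binomial(n, p)
            else:
                mat[i, j] = rng.poisson(mu)
    return pd.DataFrame(mat, index=[f[0] for f in features], columns=names)


def simulate_rna_reads(feature_seqs: dict[str, str],
                       features: list[tuple[str, int, dict[str, float]]],
                       design: list[LibraryDesign],
                       genome: list[SequenceRecord],
                       read_length: int, dispersion: float,
                       seed: int) -> dict[str, list[SequenceRecord]]:
    """One read set per library: feature reads per the NB count model plus
    background genomic reads filling each library to its design size."""
    rng = np.random.default_rng(seed)
    counts = simulate_rna_counts(features, design, dispersion,
                                 int(rng.integers(2**31)))
    out: dict[str, list[SequenceRecord]] = {}
    for lib in design:
        reads: list[SequenceRecord] = []
        k = 0
        for fid, _length, _levels in features:
            c = int(counts.loc[fid, lib.name])
            seq = feature_seqs[fid]
            span = len(seq) - read_length
            for _ in range(c):
                s = int(rng.integers(0, max(span, 0) + 1))
                r = seq[s:s + read_length] if span >= 0 else seq
                if rng.random() < 0.5:
                    r = reverse_complement(r)
                reads.append(SequenceRecord(f"{lib.name}_r{k}", r))
                k += 1
        n_bg = max(lib.library_size - len(reads), 0)
        bg = simulate_dna_reads(genome, n_bg * read_length / max(
            sum(len(c) for c in genome), 1), read_length, 0.0,
            int(rng.integers(2**31)))
        for r in bg[:n_bg]:
            reads.append(SequenceRecord(f"{lib.name}_bg{r.id}", r.residues))
        out[lib.name] = reads[:lib.library_size]
    return out
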