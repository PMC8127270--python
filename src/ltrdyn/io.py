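"""Readers/writers for the formats the pipeline touches.

All internal interval arithmetic is 0-based half-open; GFF3 (1-based closed)
is converted at the I/O boundary and nowhere else.  FASTA/FASTQ parsing is
done with explicit line tracking so that malformed input is reported with a
line number.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("ltrdyn")

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")
VALID_STRANDS = {"+", "-"}


class ParseError(ValueError):
    """Raised on malformed input; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named DNA sequence (genome contig, element, LTR...)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # convenience
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene with 0-based half-open coordinates and its GO annotation."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.id}: unknown strand {self.strand!r}")


@dataclass
class LTRElement:
    """A detected full-length element with its annotation as it accretes
    through the pipeline (lineage, age, expression are filled in later
    stages and default to None)."""

    id: str
    chrom: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    similarity: float
    tsd: str | None = None
    nested: bool = False
    superfamily: str | None = None
    lineage: str | None = None
    autonomous: bool | None = None
    age_years: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PipelineConfig:
    """All run parameters, with defaults matching the published analysis."""

    # structural detection
    min_ltr_len: int = 100
    max_ltr_len: int = 6000
    min_elem_len: int = 1500
    max_elem_len: int = 25000
    tsd_len: int = 5
    min_similarity: float = 85.0
    vicinity: int = 10
    seed_kmer: int = 20
    require_tsd: bool = True
    # redundancy clustering
    cluster_identity: float = 90.0
    # dating
    substitution_rate: float = 2.36e-9
    # read mapping
    map_min_identity: float = 0.9
    map_min_len_frac: float = 0.9
    # expression
    window: int = 50000
    expressed_rpkm: float = 1.0
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_ltr_len < self.max_ltr_len):
            raise ValueError("LTR length bounds must satisfy 0 < min < max")
        if not (0 < self.min_elem_len < self.max_elem_len):
            raise ValueError("element length bounds must satisfy 0 < min < max")
        if not (0 < self.min_similarity <= 100):
            raise ValueError("min_similarity must be in (0, 100]")
        for name in ("tsd_len", "vicinity", "seed_kmer", "window"):
            if getattr(self, name) <= 0 and name != "vicinity":
                raise ValueError(f"{name} must be positive")
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be positive")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) FASTA file.

    Raises ParseError with a line number on malformed headers, non-IUPAC
    residues, or duplicate record ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal cur_id, chunks
        if cur_id is None:
            return
        if cur_id in seen:
            raise ParseError(f"{path}: duplicate record id {cur_id!r} (line {lineno})")
        seen.add(cur_id)
        records.append(SequenceRecord(cur_id, "".join(chunks), cur_desc))
        cur_id, chunks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                seq = line.strip().upper()
                bad = set(seq) - _IUPAC_DNA
                if bad:
                    raise ParseError(
                        f"{path}: non-IUPAC residue(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
        flush(lineno + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def parse_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a 4-line-per-record FASTQ file (qualities are discarded)."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        # trailing blank lines are tolerated
        while lines and not lines[-1]:
            lines.pop()
        if len(lines) % 4 != 0:
            raise ParseError(f"{path}: FASTQ record count not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}: expected '@' header at line {i + 1}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: expected '+' separator at line {i + 3}")
        if len(seq) != len(qual):
            raise ParseError(f"{path}: sequence/quality length mismatch at line {i + 2}")
        records.append(SequenceRecord(head[1:].split()[0], seq))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{quality_char * len(rec.residues)}\n")


# ---------------------------------------------------------------------------
# GFF3 and annotation sidecars
# ---------------------------------------------------------------------------

def parse_gff3(path: str | Path, go_table: str | Path | None = None,
               feature_type: str = "gene") -> list[GeneModel]:
    """Read gene-typed features from a GFF3 file.

    1-based closed input coordinates are converted to the internal 0-based
    half-open convention.  GO terms, if any, come from a companion
    two-column TSV (gene id, GO id) because gene-function sidecar tables
    are not part of GFF3 itself.
    """
    go_map: dict[str, set[str]] = {}
    if go_table is not None:
        go_map = parse_go_tsv(go_table)

    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: expected 9 columns at line {lineno}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            start1, end1 = int(start_s), int(end_s)
            if start1 > end1:
                raise ParseError(f"{path}: start > end at line {lineno}")
            if strand not in VALID_STRANDS:
                raise ParseError(f"{path}: unknown strand {strand!r} at line {lineno}")
            gid = _gff_attr(attrs, "ID") or f"{feature_type}_{lineno}"
            genes.append(GeneModel(gid, chrom, start1 - 1, end1, strand,
                                   set(go_map.get(gid, ()))))
    return genes


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def parse_go_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: gene id <tab> GO id, one pair per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: expected 2 columns at line {lineno}")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_element_gff(elements: Sequence[LTRElement], path: str | Path) -> None:
    """Write elements as GFF3: one LTR_retrotransposon parent with two
    long_terminal_repeat children each; coordinates 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            attrs = [f"ID={el.id}", f"similarity={el.similarity:.2f}"]
            if el.tsd:
                attrs.append(f"tsd={el.tsd}")
            if el.nested:
                attrs.append("nested=true")
            fh.write("\t".join([
                el.chrom, "ltrdyn", "LTR_retrotransposon",
                str(el.start + 1), str(el.end), ".", "+", ".",
                ";".join(attrs),
            ]) + "\n")
            for tag, (s, e) in (("5ltr", (el.ltr5_start, el.ltr5_end)),
                                ("3ltr", (el.ltr3_start, el.ltr3_end))):
                fh.write("\t".join([
                    el.chrom, "ltrdyn", "long_terminal_repeat",
                    str(s + 1), str(e), ".", "+", ".",
                    f"ID={el.id}_{tag};Parent={el.id}",
                ]) + "\n")


def parse_element_gff(path: str | Path) -> list[LTRElement]:
    """Round-trip reader for write_element_gff output."""
    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, _s, ftype, start_s, end_s, _sc, _st, _ph, attrs = fields
            start, end = int(start_s) - 1, int(end_s)
            if ftype == "LTR_retrotransposon":
                eid = _gff_attr(attrs, "ID")
                sim = float(_gff_attr(attrs, "similarity") or 0.0)
                parents[eid] = {
                    "chrom": chrom, "start": start, "end": end, "sim": sim,
                    "tsd": _gff_attr(attrs, "tsd"),
                    "nested": _gff_attr(attrs, "nested") == "true",
                }
                order.append(eid)
            elif ftype == "long_terminal_repeat":
                parent = _gff_attr(attrs, "Parent")
                cid = _gff_attr(attrs, "ID") or ""
                key = "ltr5" if cid.endswith("_5ltr") else "ltr3"
                parents[parent][key] = (start, end)
    out = []
    for eid in order:
        p = parents[eid]
        out.append(LTRElement(
            id=eid, chrom=p["chrom"], start=p["start"], end=p["end"],
            ltr5_start=p["ltr5"][0], ltr5_end=p["ltr5"][1],
            ltr3_start=p["ltr3"][0], ltr3_end=p["ltr3"][1],
            similarity=p["sim"], tsd=p["tsd"], nested=p["nested"],
        ))
    return out


def write_element_bed(elements: Sequence[LTRElement], path: str | Path) -> None:
    """BED6 export (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for el in elements:
            fh.write("\t".join([
                el.chrom, str(el.start), str(el.end), el.id,
                f"{el.similarity:.2f}", "+",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Flat key=value configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key=value file into a PipelineConfig; unknown keys error."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}: expected key=value at line {lineno}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ParseError(f"{path}: unknown config key {key!r} (line {lineno})")
            ftype = fields[key].type
            if ftype == "bool":
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif ftype == "int":
                kwargs[key] = int(val)
            elif ftype == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(PipelineConfig):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")
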