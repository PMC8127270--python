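# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ltrdyn`.

## Coordinate conventions and I/O

All internal intervals are 0-based half-open; GFF3 (1-based closed) is
converted only at the I/O boundary. FASTA/FASTQ/GFF3 parsing is done with
explicit line tracking so malformed input errors name the offending line.
GO annotations travel in a two-column TSV sidecar (gene id, GO id) rather
than GFF attributes, since gene-function tables are not part of GFF3.

## Synthetic data generator

The generator defines the package's standard study conditions; every
downstream claim made by the test suite is a claim about data of this
shape.

* **Genome layout.** Planted full-length elements, solo-LTR decoys and
  genes are placed on one contig (default 1.5 Mbp) at non-overlapping
  positions with ≥ 1 kbp spacing; gap lengths are multinomially
  distributed so the contig length is exact. Truncated copies and
  internal-region fragment copies (which implement per-element genomic
  copy numbers) go on a second contig, with same-family copies kept
  ≥ 26 kbp apart so family redundancy cannot masquerade as a paired-LTR
  structure.
* **Elements.** Default 20 elements across 4 lineages (Ale, Angela:
  *Copia*; Tekay, CRM: *Gypsy*), LTRs 300–800 bp, internal regions
  1.6–3.2 kbp, total length within the detector's 1.5–25 kbp bounds, 5-bp
  TSD duplicated at both flanks. Autonomous elements (70%) carry all five
  domain cassettes in superfamily order; non-autonomous elements lose 1–2
  cassettes. Cassettes are reverse-translated with randomised synonymous
  codons per element copy: the encoded protein is exact while cassette DNA
  differs between copies, so protein-level annotation stays trivially
  verifiable without creating genomic repeats that are not LTRs.
* **Ages.** Per-lineage mean ages (3–9 MY) with uniform ±70% spread. Both
  LTRs mutate independently with per-site substitution probability
  age × rate (transitions twice as likely as transversions, so both K2P
  log terms are exercised); expected pairwise divergence is 2 r T,
  consistent with dividing K by 2r when dating. The internal region
  mutates at the same per-copy rate. Saturation (age × rate ≥ 0.75) is
  rejected.
* **Expression.** 30% of elements are expressed, with levels 3–20 on the
  RPKM scale, decaying with age (young copies are the transcribed ones);
  2 elements carry a planted 4-fold salt response at 48 d. RNA counts per
  library are negative-binomial with dispersion 0.1 (0.05 in the DE
  benchmark) around level × (length/10³) × (library size/10⁶), so the
  RPKM recomputed from a library of the design size equals the planted
  level in expectation. The published work does not report its data's
  dispersion or library sizes; these defaults are the package's own and
  are chosen so that expressed elements receive tens of reads per library.
* **Genes and GO.** 60 genes (0.6–1.5 kbp) with lognormal expression;
  genes within 50 kbp of an expressed element have levels inflated 3-fold
  and draw preferentially from a 4-term "enriched" GO subset, giving the
  proximity and enrichment statistics a planted effect to find.
* **Reads.** DNA reads are uniform over both strands with read count
  round(coverage × genome length / read length) and substitution errors
  only. RNA reads (when generated at read level) are drawn from feature
  sequences per the NB counts, topped up with background genomic reads to
  the design library size. No indels, no quality-score realism, no
  paired ends.

What passing tests on these data do *not* show: robustness to indel
divergence between LTRs (the aligner handles gaps but the generator never
produces them), to nested insertions (constructed only in targeted tests),
to organellar contamination, or to the fragmented, repeat-collapsed
assemblies of short-read genomes.

## Structural detection

Three stages per contig:

1. **Seeding.** All maximal exact direct repeats of length ≥ 20 (k-mer
   index, co-diagonal runs merged) with start separation ≤ 25 kbp.
2. **Chaining + extension.** Co-linear seeds (diagonals within 20 bp,
   gaps ≤ 800 bp) are chained; chain ends are extended outward by
   ungapped X-drop extension (match +1, mismatch −2, drop 12), which
   tolerates the substitution divergence of genuine LTR pairs but stops
   within a few bases of the repeat boundary in random flanks.
3. **Filtering.** Both LTR lengths in [100, 6000], element span in
   [1500, 25000], global-alignment identity ≥ 85% (gaps count as
   mismatches; the identity denominator is the full column count — the
   published analysis does not define its denominator), ≤ 10% N content.
   Overlapping candidates keep the higher-similarity one. The TSD search
   tries boundary shifts up to ±10 bp (smallest total shift, then
   leftmost, wins) and snaps boundaries to the TSD; candidates without a
   TSD are flagged and, by default (`require_tsd`), excluded, as are
   candidates nested inside another element's internal region. No
   TG…CA terminal-motif requirement is imposed.

The ungapped extension is a deliberate simplification: with
substitution-only divergence it is exact, and the TSD snap corrects the
±few-bp extension noise (observed mean boundary error ≈ 0.1 bp). LTR
pairs with indel divergence would need banded gapped extension; this is a
known limitation.

Redundancy clustering is greedy-incremental at 90% identity: sequences
sorted by descending length; each joins the first representative aligning
at ≥ 90% identity, computed from a full-query infix alignment of the
shorter sequence inside the longer (which covers ≥ 80% of the shorter by
construction); otherwise it founds a cluster.

## Domain annotation

Each reference protein is Smith–Waterman-aligned (BLOSUM62, gap open 11 /
extend 1) against all six translation frames; hits need ≥ 40% identity
over aligned columns and ≥ 50% reference coverage, keeping the best hit
per domain. The bundled reference is a synthetic stand-in (randomly
generated proteins, one GAG/PR/INT/RT/RH set per lineage for Ale, Angela,
Tekay, CRM); real references can be supplied as protein FASTA with
`>NAME|DOMAIN|SUPERFAMILY|LINEAGE` headers. The 40%/50% thresholds are
chosen for protein-level detection of diverged domains; the cited
annotation tools' internal defaults are not recoverable. Classification:
INT/RT order on the coding strand (majority frame sign decides the
strand) gives the superfamily, falling back to the majority superfamily
label; lineage is the modal label (ties by summed score, then
alphabetically); autonomy requires all five domains. Conflicting hit sets
are classified by majority vote and flagged `conflicting` rather than
demoted to unknown.

## Dating

LTR pairs are globally aligned (match +5, mismatch −4, gap open 16
charged on the first gap column, extend 4; co-optimal alignments resolved
by the aligner's deterministic enumeration order). Gap columns and
ambiguous bases are excluded from P, Q and the site count — the standard
behaviour of pairwise distance tools; the published analysis does not
state its convention. K2P saturation (either log argument ≤ 0) and short
alignments (< 50 comparable sites) are flagged, not raised. One rate for
all lineages; ages in years, summaries in MY.

## Quantification

* **Mapping.** K-mer prefilter (13-mers, both read orientations) then
  edlib infix alignment. The ≥ 90% aligned-length fraction is implemented
  as full-query infix alignment: the entire read must align inside the
  reference and identity is computed over the read length, so overhanging
  or partial alignments fail through edit distance. Multi-mapping reads
  count once, to their best-scoring (primary) reference — ties broken by
  a seeded, logged shuffle of reference ids — and carry `unique=False`.
* **Abundance.** Average coverage = aligned bases of primary assignments
  / element length; a per-million-reads normalised column is reported
  alongside, since the published coverage statistic does not state a
  library-size normalisation.
* **Expression.** RPKM with library totals taken from the design (total
  mapped/sequenced reads), expressed = RPKM strictly > 1 in ≥ 1 library,
  per-treatment expressed sets and their 4-way Venn intersections.
* **Differential expression.** A negative-binomial exact test conditioned
  on the pooled count: counts are scaled to a common library size, the
  common dispersion φ is a ratio-of-sums method-of-moments estimate of
  (var − mean)/mean² pooled over elements and groups (φ ≤ 0 falls back to
  the Poisson/binomial conditional), group sums are NB(nμ, n/φ), and the
  two-sided p-value is the mass of all splits no more probable than the
  observed one. This approximates the pairwise exact test of the edgeR
  family without vendoring it (no TMM, no trended/tagwise dispersion);
  measured operating points on the synthetic conditions: ~100% recall on
  4-fold changes at means ≥ 50 (3 vs 3, φ = 0.05) and ~5% type-I error at
  nominal 5%. Calls additionally require fold change > 2 or < ½.
  Fold changes use a 10⁻⁸ pseudo-count guard; BH-FDR across elements.

Library totals should be transcriptome-wide totals, not the sum of the
element count matrix: normalising an element-only matrix by its own
column sums absorbs genuine induction into the normalisation
(composition bias) and deflates fold changes.

## Proximity, categories, GO

Gene–element pairs within 50 kbp (interval tree, verified against a
quadratic scan) with gap distance (0 on overlap). RPKM categories are
half-open on the left — [0,1) not, [1,10) low, [10,100) medium,
[100,∞) high — so boundary values are assigned exactly once; the
published bounds leave the boundary points unassigned. A gene near both
an expressed and a non-expressed element counts in the near-expressed
group (activity dominates). Category tests are two-sided Fisher with
BH-FDR over the 4 categories; GO over-representation is one-sided Fisher
over terms with ≥ 1 selected gene, BH-FDR < 0.05, no ontology-graph
propagation (annotations used as given).

## Trend statistics

One-way ANOVA (scipy) with Tukey HSD (Tukey–Kramer for unequal n) and a
compact letter display built by insert-and-absorb over the
non-significance graph, letters ordered by descending group mean;
all-equal zero-variance input is reported non-significant rather than
raising. Values enter untransformed (a log10(x+1) option exists).
Percentages round half-up to 2 decimals. OLS regressions report slope,
intercept, Pearson r and a two-sided t-test p (n ≥ 3). The slope table
regresses per-treatment (C24/S24/C48/S48) mean RPKM on insertion age and
on coverage for *Copia* elements only — *Gypsy* expression is too low to
regress on — and slope differences between treatments are descriptive
(no interaction test).

## Problem sizes

The default end-to-end dataset (1.5-Mbp genome, 20 elements, 60 genes,
12 libraries at 10⁶ reads, 5× DNA coverage) runs in well under a minute;
RNA expression runs from NB count tables at the design library size,
which keeps RPKM granularity at 1 count ≈ 1 RPKM for a 1-kbp feature,
while read-level RNA mapping is exercised on smaller sets. The
structural-detection benchmark is a 100-kbp genome with 20 elements and
10 decoys; dating recovery uses 100 replicate 1000-bp LTR pairs per age.

## Known limitations

* Detection extension is ungapped; indel-diverged LTR pairs will be
  found only via their seed chains and may get biased boundaries.
* The DE test is an approximation of the cited exact-test framework (no
  TMM normalisation, common dispersion only).
* The bundled domain reference is synthetic; real annotation requires a
  user-supplied protein reference.
* Reverse-complement (inverted) element orientation, PBS/PPT annotation
  and solo-LTR-based deletion-rate estimation are out of scope.
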