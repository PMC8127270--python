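# ltrdyn

Full-length LTR retrotransposon characterisation and dynamics analysis for
plant genomes: structural detection of paired-LTR elements, lineage
classification from protein domains, insertion-age dating from LTR
divergence, coverage-based genomic abundance, RPKM expression with
differential-expression calls under a salinity-stress design, gene-proximity
and GO-enrichment statistics, and the age/abundance/expression trend
analysis — all exercisable end to end on synthetic genomes with planted
ground truth.

## Who this is for

Researchers studying transposable-element dynamics who want a tested,
scriptable re-implementation of the standard full-length LTR-RE workflow
(detect → classify → date → quantify → relate to genes), plus a synthetic
data generator that makes every stage verifiable without touching real
sequencing archives.

## The science in brief

**Detection.** A full-length LTR retroelement is a pair of similar direct
repeats (the LTRs, 100–6000 bp each) spanning 1.5–25 kbp, flanked by a 5-bp
target-site duplication (TSD), with LTR–LTR alignment identity ≥ 85% and a
TSD search vicinity of ±10 bp. Detected elements are de-redundified by
greedy clustering at 90% identity.

**Classification.** The internal region is scanned against protein domain
references (GAG, PR, INT, RT, RH) in all six frames. Domain order on the
coding strand separates the superfamilies — integrase upstream of reverse
transcriptase ⇒ *Copia*, downstream ⇒ *Gypsy* — and the modal reference
lineage labels the element. An element is autonomous iff all five domains
are present.

**Dating.** The two LTRs are identical at insertion and then diverge.
From a global LTR–LTR alignment with transition proportion *P* and
transversion proportion *Q* over gap-free columns, the Kimura two-parameter
distance is

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and the insertion age is T = K / (2r) with r = 2.36 × 10⁻⁹
substitutions/site/year (twice the *Populus trichocarpa* synonymous rate).

**Quantification.** Reads map to elements at ≥ 90% identity over ≥ 90% of
the read. Genomic abundance is average coverage (aligned bases / element
length); expression is RPKM = c · 10⁹ / (N · L) for c reads on an element
of L bp in a library of N mapped reads. An element is *expressed* iff
RPKM > 1 in ≥ 1 of the 12 libraries (2 conditions × 2 timepoints × 3
replicates); it is differentially expressed iff |fold change| > 2 and
BH-FDR < 0.05 under a conditional negative-binomial exact test.

**Gene proximity.** Genes within 50 kbp of an element are binned into four
RPKM categories ([0,1), [1,10), [10,100), [100,∞)); category differences
between genes near expressed vs. non-expressed elements use two-sided
Fisher tests with BH-FDR, and GO over-representation uses one-sided Fisher
tests with BH-FDR. Trends among age, abundance and expression are OLS
regressions (per-lineage comparisons by one-way ANOVA + Tukey HSD with a
compact letter display).

## Worked example

Simulate a 1.5-Mbp genome with 20 planted elements (4 lineages, known ages
and expression levels), 10 decoys and 60 genes, then run every stage:

```bash
ltrdyn run --seed 1 --outdir out/
```

prints

```json
{
  "n_truth": 20,
  "n_detected": 20,
  "recall": 1.0,
  "mean_boundary_error": 0.1,
  "n_clusters": 20,
  "n_expressed": 6,
  "dna_unique_fraction": 1.0,
  "n_de_24": 0,
  "n_de_48": 2,
  "n_proximal_pairs": 67,
  "n_proximal_genes": 50,
  "n_enriched_go": 4,
  "outdir": "out/"
}
```

All 20 planted elements are recovered with a mean boundary error of 0.1 bp
and no decoy called; 6 elements exceed the RPKM > 1 expression threshold
(the planted expressed fraction); the 2 planted salt-responsive elements
are the 2 differential-expression calls at 48 d; 50 genes lie within
50 kbp of an element and 4 GO terms (the planted enriched set) are
over-represented near expressed elements. Result tables (`elements.gff3`,
`ages.tsv`, `abundance.tsv`, `rpkm.tsv`, `de_48d.tsv`, `proximity.tsv`,
`go_enrichment.tsv`, `slope_table.tsv`, …) are written to `out/`.

Individual stages are available as `ltrdyn simulate | detect | annotate |
date | validate`, and as library functions (`ltrdyn.detect_full_length`,
`ltrdyn.k2p_distance`, `ltrdyn.differential_expression`, …).

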