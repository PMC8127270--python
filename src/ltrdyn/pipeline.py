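"""End-to-end run on a synthetic dataset: simulate -> detect -> annotate ->
date -> quantify -> proximity -> dynamics, emitting every result table.

DNA abundance is measured by mapping simulated whole-genome shotgun reads
to the detected elements.  RNA expression runs from negative-binomial
count tables at a realistic library size (1e6 reads), which keeps the RPKM
granularity fine without simulating millions of reads; read-level RNA
mapping is exercised separately at small scale.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import dating, detect, dynstats, proximity, quantify
from . import simulate as sim
from .io import write_element_bed, write_element_gff, write_fasta


def run_pipeline(spec: sim.SyntheticGenomeSpec, outdir: str | Path,
                 dna_fold_coverage: float = 5.0,
                 dna_read_length: int = 100,
                 dna_error_rate: float = 0.005) -> dict:
    """Run every stage on one synthetic dataset; returns a summary dict and
    writes all result tables under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # ------------------------------------------------------------- simulate
    data = sim.simulate_genome(spec)
    write_fasta(data.contigs, outdir / "genome.fasta")
    truth_df = pd.DataFrame([asdict(t) for t in data.truth])
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # --------------------------------------------------------------- detect
    params = detect.DetectionParams(tsd_len=spec.tsd_len)
    elements = detect.detect_full_length(data.contigs, params)
    write_element_gff(elements, outdir / "elements.gff3")
    write_element_bed(elements, outdir / "elements.bed")
    contig_seq = {c.id: c.residues for c in data.contigs}
    element_seqs = {
        el.id: contig_seq[el.chrom][el.start:el.end] for el in elements}
    clusters = detect.cluster_elements(
        [sim.SequenceRecord(eid, s) for eid, s in element_seqs.items()])
    pd.DataFrame(
        [{"cluster": c.representative, "member": m,
          "identity_to_representative": c.identities[m]}
         for c in clusters for m in c.members]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- annotate
    refs = ann.bundled_reference()
    annotations = {}
    for el in elements:
        internal = contig_seq[el.chrom][el.ltr5_end:el.ltr3_start]
        hits = ann.scan_domains(internal, refs)
        a = ann.classify_element(hits)
        el.superfamily, el.lineage, el.autonomous = \
            a.superfamily, a.lineage, a.autonomous
        annotations[el.id] = a
    pd.DataFrame(
        [{"element": eid, "superfamily": a.superfamily, "lineage": a.lineage,
          "autonomous": a.autonomous, "domain_order": ",".join(a.domain_order),
          "conflicting": a.conflicting}
         for eid, a in annotations.items()]
    ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    # ----------------------------------------------------------------- date
    dparams = dating.DatingParams(spec.substitution_rate)
    date_rows = []
    for el in elements:
        ltr5 = contig_seq[el.chrom][el.ltr5_start:el.ltr5_end]
        ltr3 = contig_seq[el.chrom][el.ltr3_start:el.ltr3_end]
        aln = dating.align_ltrs(ltr5, ltr3)
        try:
            est = dating.k2p_distance(aln)
            age = dating.insertion_time(est, dparams)
            row = {"element": el.id, "P": est.P, "Q": est.Q, "K": est.K,
                   "years": age.years, "flag": age.flag}
        except dating.SaturationError:
            row = {"element": el.id, "P": np.nan, "Q": np.nan, "K": np.nan,
                   "years": np.nan, "flag": "saturated"}
        el.age_years = row["years"]
        date_rows.append(row)
    pd.DataFrame(date_rows).to_csv(outdir / "ages.tsv", sep="\t", index=False)

    # ------------------------------------------------- DNA abundance (reads)
    dna_reads = sim.simulate_dna_reads(data.contigs, dna_fold_coverage,
                                       dna_read_length, dna_error_rate,
                                       int(rng.integers(2**31)))
    references = [sim.SequenceRecord(eid, s) for eid, s in element_seqs.items()]
    assignments = quantify.map_reads(dna_reads, references,
                                     seed=int(rng.integers(2**31)))
    lengths = {eid: len(s) for eid, s in element_seqs.items()}
    abundance = quantify.average_coverage(assignments, lengths,
                                          n_reads_total=len(dna_reads))
    dna_unique = (float(np.mean([a.unique for a in assignments]))
                  if assignments else 1.0)
    pd.DataFrame(
        [{"element": r.element_id, "coverage": r.coverage,
          "coverage_per_million_reads": r.coverage_per_million}
         for r in abundance.values()]
    ).to_csv(outdir / "abundance.tsv", sep="\t", index=False)

    # --------------------------------------------------- RNA expression (NB)
    design = sim.full_design(spec.library_size)
    truth_by_id = {t.id: t for t in data.truth}
    # detected elements inherit the planted levels of the truth element they
    # overlap; unmatched detections are silent
    def planted_levels(el):
        for t in data.truth:
            if t.chrom == el.chrom and t.start < el.end and el.start < t.end:
                return t.expression
        return {tr: 0.0 for tr in sim.TREATMENTS}

    el_features = [(el.id, lengths[el.id], planted_levels(el))
                   for el in elements]
    gene_lengths = {g.id: g.end - g.start for g in data.genes}
    gene_features = [(g.id, gene_lengths[g.id], data.gene_levels[g.id])
                     for g in data.genes]
    counts = sim.simulate_rna_counts(el_features + gene_features, design,
                                     spec.dispersion,
                                     int(rng.integers(2**31)))
    totals = pd.Series({d.name: d.library_size for d in design})
    all_lengths = dict(lengths) | gene_lengths
    rpkm_all = quantify.rpkm(counts, all_lengths, totals)
    el_ids = [el.id for el in elements]
    rpkm_el = rpkm_all.loc[el_ids]
    rpkm_genes = rpkm_all.loc[[g.id for g in data.genes]]
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    rpkm_all.to_csv(outdir / "rpkm.tsv", sep="\t")

    expressed = quantify.call_expressed(rpkm_el)
    sets, member, venn = quantify.condition_sets(rpkm_el, design)
    member.to_csv(outdir / "expressed_sets.tsv", sep="\t")
    pd.DataFrame(
        [{"C24": k[0], "S24": k[1], "C48": k[2], "S48": k[3], "count": v}
         for k, v in sorted(venn.items())]
    ).to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)

    de_tables = {}
    for tp in (24, 48):
        de = quantify.differential_expression(counts.loc[el_ids], design, tp,
                                              library_totals=totals)
        de_df = pd.DataFrame([asdict(r) for r in de])
        de_df.to_csv(outdir / f"de_{tp}d.tsv", sep="\t", index=False)
        de_tables[tp] = de_df

    # ------------------------------------------------------------ proximity
    prox = proximity.genes_near_elements(data.genes, elements,
                                         expressed=expressed)
    pd.DataFrame([asdict(r) for r in prox]).to_csv(
        outdir / "proximity.tsv", sep="\t", index=False)
    gene_rpkm_mean = rpkm_genes.mean(axis=1).to_dict()
    cat_table = proximity.category_table(prox, gene_rpkm_mean)
    cat_tests = proximity.compare_categories(cat_table)
    cat_tests.to_csv(outdir / "category_tests.tsv", sep="\t")

    near_expr_genes = {r.gene_id for r in prox if r.element_expressed}
    background = {g.id for g in data.genes}
    enrichment = (proximity.go_enrichment(near_expr_genes, background,
                                          data.gene_go)
                  if near_expr_genes else [])
    pd.DataFrame([asdict(r) for r in enrichment]).to_csv(
        outdir / "go_enrichment.tsv", sep="\t", index=False)

    # -------------------------------------------------------------- dynamics
    ann_pairs = [(el.superfamily or "unknown", el.lineage or "unknown")
                 for el in elements]
    dynstats.lineage_summary(ann_pairs).to_csv(
        outdir / "lineage_summary.tsv", sep="\t", index=False)
    treatment_means = {
        t: rpkm_el[[d.name for d in design if d.treatment == t]].mean(axis=1)
        for t in sim.TREATMENTS}
    joined = pd.DataFrame({
        "element": el_ids,
        "superfamily": [el.superfamily for el in elements],
        "lineage": [el.lineage for el in elements],
        "age_years": [el.age_years for el in elements],
        "coverage": [abundance[eid].coverage for eid in el_ids],
    }).set_index("element")
    for t in sim.TREATMENTS:
        joined[f"rpkm_{t}"] = treatment_means[t]
    joined.to_csv(outdir / "joined.tsv", sep="\t")
    slopes = dynstats.slope_table(joined.reset_index())
    slopes.to_csv(outdir / "slope_table.tsv", sep="\t", index=False)

    by_lineage = {lin: grp["age_years"].dropna().tolist()
                  for lin, grp in joined.groupby("lineage")
                  if len(grp) >= 2}
    anova_df = pd.DataFrame()
    if len(by_lineage) >= 2:
        res = dynstats.anova_tukey(by_lineage)
        anova_df = pd.DataFrame(
            [{"group": g, "mean": res.group_means[g],
              "letters": res.letters[g], "F": res.f_statistic,
              "p_value": res.p_value} for g in by_lineage])
        anova_df.to_csv(outdir / "age_anova.tsv", sep="\t", index=False)

    recovered = _recall(data.truth, elements)
    return _pyify({
        "n_truth": len(data.truth),
        "n_detected": len(elements),
        "recall": recovered["recall"],
        "mean_boundary_error": recovered["mean_boundary_error"],
        "n_clusters": len(clusters),
        "n_expressed": len(expressed),
        "dna_unique_fraction": dna_unique,
        "n_de_24": int((de_tables[24]["status"] != "ns").sum()),
        "n_de_48": int((de_tables[48]["status"] != "ns").sum()),
        "n_proximal_pairs": len(prox),
        "n_proximal_genes": len({r.gene_id for r in prox}),
        "n_enriched_go": sum(bool(r.enriched) for r in enrichment),
        "outdir": str(outdir),
    })


def _pyify(d: dict) -> dict:
    """Native Python scalars only (JSON-serialisable summary)."""
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            out[k] = int(v)
        elif isinstance(v, (np.floating,)):
            out[k] = float(v)
        else:
            out[k] = v
    return out


def _recall(truth, elements, tol: int = 10) -> dict:
    """Fraction of planted elements recovered with boundary error <= tol."""
    hits = 0
    errors = []
    for t in truth:
        for el in elements:
            if el.chrom != t.chrom:
                continue
            err = max(abs(el.start - t.start), abs(el.end - t.end))
            if err <= tol:
                hits += 1
                errors.append(err)
                break
    return {"recall": hits / len(truth) if truth else 1.0,
            "mean_boundary_error": float(np.mean(errors)) if errors else 0.0}
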