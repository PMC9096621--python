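"""De novo sRNA clusters: calling, categorization, and sCTGR methylation.

18-24 nt reads pooled across samples are merged into coverage islands
(gap <= 75 bp, >= 3 supporting reads); each cluster is categorized by
precedence gene_body > promoter > TE > intergenic; the genomic interval a
cluster covers (its sCTGR) is then scored for differential methylation.
"""

from collections import Counter

from photoepi import (
    SimulationConfig, call_clusters, categorize_clusters, clusters_to_count_matrix,
    cpm_filter, nb_test, promoter_regions, sctgr_methylation,
    simulate_genome, simulate_methylomes, simulate_srna_reads,
)

cfg = SimulationConfig(seed=42)
seqs, annotation = simulate_genome(cfg)
reads, truth = simulate_srna_reads(seqs, annotation, cfg)
clusters = call_clusters(reads)
genes = [m for m in annotation if m.feature_class == "gene"]
promoters = promoter_regions(genes, 2000, {c: len(s) for c, s in seqs.items()})
categorize_clusters(clusters, annotation, promoters)
print(f"{len(clusters)} sRNA clusters:", dict(Counter(c.category for c in clusters)))

groups = ["WT"] * 3 + ["mut"] * 3
cm = cpm_filter(clusters_to_count_matrix(clusters), 2, groups=groups)
de = nb_test(cm, groups)
n_diff = sum(r.status != "ns" for r in de)
print(f"differentially accumulated clusters at FDR 0.05: {n_diff} "
      f"(planted: {len(truth.diff_cluster_lfc)})")

reports, _ = simulate_methylomes(seqs, annotation, cfg)
dm = sctgr_methylation(clusters[:50], reports["WT"], reports["mut"], contexts=("CHH",))
n_5pct = int(dm["meets_min_diff"].sum())
print(f"of the first 50 sCTGRs, {n_5pct} show >= 5% CHH methylation difference")
# Cluster counts feed the same NB test as genes; the 5% floor is the
# effect-size gate used when associating sRNA accumulation with methylation.
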