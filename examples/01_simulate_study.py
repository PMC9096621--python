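"""Generate a miniature multi-omics study with planted ground truth.

The generator emulates the structure of a phytochrome-mutant fruit
experiment: a small tomato-like genome (GC 0.36, gene-rich arms, TE-rich
pericentromere), one pooled bisulfite sample per genotype with context
means near CG 80% / CHG 67% / CHH 23%, NB-distributed gene counts for
3 + 3 replicates, and sRNA reads concentrated at discrete loci.
"""

from photoepi import SimulationConfig, simulate_counts, simulate_genome, simulate_methylomes

cfg = SimulationConfig(seed=42)
seqs, annotation = simulate_genome(cfg)
genes = [m for m in annotation if m.feature_class == "gene"]
tes = [m for m in annotation if m.feature_class == "TE"]
print(f"genome: {len(seqs)} chromosomes x {cfg.chrom_len/1e3:.0f} kb, "
      f"{len(genes)} genes, {len(tes)} TEs")

reports, truth = simulate_methylomes(seqs, annotation, cfg)
wt = reports["WT"]
for ctx in ("CG", "CHG", "CHH"):
    sub = wt[wt["context"] == ctx]
    level = sub["meth"].sum() / sub["total"].sum()
    print(f"  WT {ctx} methylation level: {level:.3f}  ({len(sub):,} cytosines)")
print(f"  planted differentially methylated promoter regions: {len(truth.dmr_regions)} "
      f"(context {cfg.dmr_context}, |delta| = {cfg.dmr_delta})")

counts, ct = simulate_counts(annotation, cfg, kind="gene")
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"{len(ct.deg_lfc)} planted DEGs at |log2FC| = {cfg.deg_lfc}")
# The WT context means should sit near the study's 0.80 / 0.67 / 0.23;
# everything planted here is what the downstream stages must recover.
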