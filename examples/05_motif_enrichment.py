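"""Positional TF-binding-site enrichment with a permutation null.

A PFM becomes a log-odds PWM whose hit threshold comes from the exact null
score distribution (p < 1e-5); 20-kb upstream regions are scanned on both
strands; the cumulative fraction of genes with a hit within x bp of the TSS
is compared between a regulated set and all genes, and max-ES significance
comes from 1,000 same-size random gene sets.
"""

import numpy as np

from photoepi import (
    PWM, SimulationConfig, enrichment_test, make_demo_pfm, pwm_scan,
    simulate_genome, simulate_motif_landscape, upstream_regions,
)

cfg = SimulationConfig(seed=42)
seqs, annotation = simulate_genome(cfg)
genes = [m for m in annotation if m.feature_class == "gene"]
gene_ids = [g.gene_id for g in genes]

# 1. sequence-level scanning with the bundled E-box-like PWM
pwm = PWM.from_pfm(make_demo_pfm())
regions = upstream_regions(genes, {c: len(s) for c, s in seqs.items()})
hits = pwm_scan(seqs, regions, pwm, p_threshold=1e-5)
print(f"sequence scan: {len(hits)} hits above the exact p<1e-5 threshold "
      f"in {len(regions)} x 20 kb upstream regions")

# 2. planted positional landscape: enriched genes carry an extra
#    TSS-proximal occurrence with probability 0.6 within 1 kb
land_hits, truth = simulate_motif_landscape(annotation, cfg)
res = enrichment_test(land_hits, truth.enriched_gene_set[:100], gene_ids,
                      n_perm=1000, seed=42)
i_max = int(np.argmax(res.es))
print(f"planted enrichment: max ES = {res.summary_es:.3f} at {res.positions[i_max]} bp, "
      f"z = {res.z:.2f}, permutation p = {res.p_perm:.4g}")
# A z above ~3 with p near 1/1001 means the regulated set gains
# motif-bearing genes much faster near the TSS than random sets do.
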