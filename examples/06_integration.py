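"""Cross-omics integration: DEG x DMP overlap, sRNA-methylation association,
and promoter-vs-gene-body sRNA effects on expression.

Runs the full pipeline on the bundled demo configuration and then reads the
integration outputs back, the same coupling-through-files the CLI uses.
"""

import json
import tempfile
from pathlib import Path

from photoepi.validation import golden_run

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "run"
    golden_run(out)
    summary = json.load(open(out / "integration_summary.json"))

    ov = summary["deg_dmp_overlap"]
    print(f"DEGs: {ov['n_deg']}, genes with DMPs: {ov['n_dmp']}, both: {ov['n_both']}")
    print(f"  -> {ov['pct_deg_with_dmp']:.1f}% of DEGs carry a differentially "
          "methylated promoter")

    assoc = summary["srna_methylation_association"]
    print(f"sRNA accumulation x sCTGR methylation 2x2 table: {assoc['table']}, "
          f"Fisher p = {assoc['p']:.3g}")
    # The 2x2 table crosses differential accumulation (FDR 0.05) with
    # differential methylation (FDR 0.05 AND >= 5% pooled difference); a
    # small p indicates the two omics layers change together.
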