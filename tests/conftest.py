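import numpy as np
import pandas as pd
import pytest

from photoepi import (
    SimulationConfig,
    promoter_regions,
    simulate_genome,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=7, n_chroms=2, chrom_len=200_000, n_genes=60, n_tes=24
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """One small simulated study shared by read-only tests."""
    seqs, ann = simulate_genome(small_cfg)
    reports, truth = simulate_methylomes(seqs, ann, small_cfg)
    genes = [m for m in ann if m.feature_class == "gene"]
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    promoters = promoter_regions(genes, 2000, chrom_lengths)
    return {
        "cfg": small_cfg,
        "seqs": seqs,
        "ann": ann,
        "genes": genes,
        "chrom_lengths": chrom_lengths,
        "promoters": promoters,
        "reports": reports,
        "truth": truth,
    }


@pytest.fixture()
def site_frame():
    """Hand-built cytosine frames for rule-level DM tests."""

    def build(rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth", "total"]
        )

    return build
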