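"""Self-validation battery: oracles, calibration, recovery, golden run.

Every check here recomputes its quantity from scratch by running the
package on freshly generated synthetic data (or exhaustive enumeration for
the oracle checks). The functions return plain dictionaries of numbers so
they can back both the test suite and the standalone acceptance script.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .core import PFM
from .diffcounts import cpm_filter, nb_test
from .methylome import assign_context, call_region_dm, promoter_regions
from .motifs import PWM, enrichment_test
from .stats import fisher_exact_vec
from .synthetic import (
    SimulationConfig,
    simulate_counts,
    simulate_genome,
    simulate_methylomes,
    simulate_motif_landscape,
)

# ---------------------------------------------------------------------------
# Oracle equivalence


def fisher_oracle_max_diff(max_margin=15):
    """Max |p - oracle| over all 2x2 tables with both row sums <= max_margin.

    The oracle enumerates the hypergeometric support from binomial
    coefficients directly (independent of scipy's hypergeom machinery).
    """
    worst = 0.0
    for t1 in range(1, max_margin + 1):
        for t2 in range(1, max_margin + 1):
            ma = np.repeat(np.arange(t1 + 1), t2 + 1)
            mb = np.tile(np.arange(t2 + 1), t1 + 1)
            p_vec = fisher_exact_vec(ma, np.full_like(ma, t1), mb, np.full_like(mb, t2))
            for i in range(ma.size):
                p_oracle = _fisher_enum(int(ma[i]), t1, int(mb[i]), t2)
                worst = max(worst, abs(p_vec[i] - p_oracle))
    return worst


def _fisher_enum(m1, t1, m2, t2):
    """Brute-force two-sided Fisher p via comb-based hypergeometric pmf."""
    k = m1 + m2
    n = t1 + t2
    denom = math.comb(n, t1)
    support = range(max(0, k - t2), min(k, t1) + 1)
    pmf = {x: math.comb(k, x) * math.comb(n - k, t1 - x) / denom for x in support}
    p_obs = pmf[m1]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def context_table_counts():
    """Counts of CG / CHG / CHH over all 64 C-initial trinucleotides.

    Checks :func:`assign_context` on + and (mirrored) - strands against the
    exhaustive trinucleotide rule; returns the per-context tallies and the
    number of strand-symmetry mismatches.
    """
    tallies = {"CG": 0, "CHG": 0, "CHH": 0}
    mismatches = 0
    comp = str.maketrans("ACGT", "TGCA")
    for b1, b2 in itertools.product("ACGT", repeat=2):
        tri = "C" + b1 + b2
        ctx = assign_context({"c": tri}, "c", 0, "+")
        tallies[ctx] += 1
        # same cytosine read on the - strand of the reverse complement
        rc = tri.translate(comp)[::-1]
        ctx_rc = assign_context({"c": rc}, "c", 2, "-")
        if ctx_rc != ctx:
            mismatches += 1
    return {**tallies, "strand_mismatches": mismatches}


def pwm_tail_max_diff(max_len=8, seed=0):
    """Max |DP tail - exhaustive tail| over random PFMs of length 2..max_len."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for L in range(2, max_len + 1):
        counts = rng.integers(0, 40, size=(4, L)).astype(float) + 1.0
        pwm = PWM.from_pfm(PFM(f"rand{L}", counts))
        scores, probs = pwm.score_distribution()
        tail_dp = np.cumsum(probs[::-1])[::-1]
        # exhaustive enumeration over all 4^L sequences
        q = pwm.quantized
        seq_scores = np.zeros(1, dtype=np.int64)
        for j in range(L):
            seq_scores = (seq_scores[:, None] + q[:, j][None, :]).ravel()
        for thr_idx in range(0, len(scores), max(1, len(scores) // 64)):
            thr = scores[thr_idx]
            exact_tail = (seq_scores >= thr).mean()
            worst = max(worst, abs(tail_dp[thr_idx] - exact_tail))
    return worst


# ---------------------------------------------------------------------------
# Type-I error calibration


def dm_null_call_rate(seed=0):
    """Fraction of promoter regions called DM on effect-free methylomes."""
    cfg = SimulationConfig(seed=seed, dmr_fraction=0.0)
    seqs, ann = simulate_genome(cfg)
    reports, _ = simulate_methylomes(seqs, ann, cfg)
    genes = [m for m in ann if m.feature_class == "gene"]
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    promoters = promoter_regions(genes, 2000, chrom_lengths)
    n_called = n_total = 0
    for ctx in ("CG", "CHG", "CHH"):
        calls = call_region_dm(reports["WT"], reports["mut"], promoters, ctx)
        n_called += sum(c.status != "ns" for c in calls)
        n_total += len(calls)
    return {"rate": n_called / n_total, "n": n_total}


def nb_null_fraction(n_seeds=10, seed0=0):
    """Mean fraction of null features at p < 0.05 over independent seeds."""
    groups = ["A"] * 3 + ["B"] * 3
    fracs = []
    n_total = 0
    for seed in range(seed0, seed0 + n_seeds):
        cfg = SimulationConfig(seed=seed, deg_fraction=0.0)
        cm, _ = simulate_counts(None, cfg, kind="gene")
        cm = cpm_filter(cm, 2.0, groups=groups)
        p = np.array([r.p for r in nb_test(cm, groups)])
        fracs.append(float((p < 0.05).mean()))
        n_total += p.size
    return {"fraction": float(np.mean(fracs)), "per_seed": fracs, "n": n_total}


def motif_null_fraction(n_reps=200, seed=0):
    """Fraction of null enrichment tests at p_perm < 0.05.

    Each repetition draws a fresh effect-free occurrence landscape and a
    fresh random "regulated" set of 100 genes.
    """
    cfg = SimulationConfig(seed=seed, motif_p_extra=0.0)
    seqs, ann = simulate_genome(cfg)
    gene_ids = [m.gene_id for m in ann if m.feature_class == "gene"]
    rng = np.random.default_rng(seed + 1)
    ps = []
    for rep in range(n_reps):
        cfg_r = SimulationConfig(seed=(seed * 100_003 + rep) % 2**31, motif_p_extra=0.0)
        hits, _ = simulate_motif_landscape(ann, cfg_r)
        regulated = rng.choice(gene_ids, size=100, replace=False).tolist()
        res = enrichment_test(
            hits, regulated, gene_ids, n_perm=999, seed=int(rng.integers(2**31))
        )
        ps.append(res.p_perm)
    ps = np.array(ps)
    return {"fraction": float((ps < 0.05).mean()), "n": n_reps}


# ---------------------------------------------------------------------------
# Parameter recovery


def dmr_recovery(seed=0):
    """Recovery of planted DMRs at 20x coverage, |delta| = 0.3.

    DMRs sit on 2-kb promoters in the CHH context (hundreds of cytosines per
    region, comfortably above the >= 15-C floor). Returns the recovered
    fraction and the sign accuracy among recovered calls.
    """
    cfg = SimulationConfig(seed=seed, coverage_mean=20.0, dmr_delta=0.3)
    seqs, ann = simulate_genome(cfg)
    reports, truth = simulate_methylomes(seqs, ann, cfg)
    genes = [m for m in ann if m.feature_class == "gene"]
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    promoters = promoter_regions(genes, 2000, chrom_lengths)
    calls = call_region_dm(reports["WT"], reports["mut"], promoters, cfg.dmr_context)
    by_id = {c.region_id: c for c in calls}
    planted = {iv.name: delta for iv, _ctx, delta in truth.dmr_regions}
    recovered = sign_ok = 0
    for gid, delta in planted.items():
        c = by_id[gid]
        if c.status != "ns":
            recovered += 1
            sign_ok += (c.diff > 0) == (delta > 0)
    return {
        "recovery": recovered / len(planted),
        "sign_accuracy": sign_ok / recovered if recovered else float("nan"),
        "n": len(planted),
    }


def deg_recovery(n_seeds=3, seed0=0):
    """Recovery of planted |log2FC| = 2 DEGs at mean CPM >= 50, n = 3 vs 3."""
    groups = ["WT"] * 3 + ["mut"] * 3
    total = hits = sign_errors = 0
    for seed in range(seed0, seed0 + n_seeds):
        cfg = SimulationConfig(seed=seed)
        cm, truth = simulate_counts(None, cfg, kind="gene")
        cm = cpm_filter(cm, 2.0, groups=groups)
        res = {r.feature_id: r for r in nb_test(cm, groups)}
        for fid, lfc in truth.deg_lfc.items():
            r = res.get(fid)
            if r is None or r.mean_cpm < 50:
                continue
            total += 1
            if r.status != "ns":
                hits += 1
                if (r.log2_fc > 0) != (lfc > 0):
                    sign_errors += 1
    return {"recovery": hits / total, "sign_errors": sign_errors, "n": total}


def motif_power(n_seeds=20, seed0=0):
    """Fraction of seeds with p_perm <= 0.001 and z > 3 on planted enrichment.

    Planted conditions: extra TSS-proximal occurrence with probability 0.6
    within 1 kb, regulated set of 100 genes.
    """
    cfg0 = SimulationConfig(seed=seed0)
    seqs, ann = simulate_genome(cfg0)
    gene_ids = [m.gene_id for m in ann if m.feature_class == "gene"]
    n_pass = 0
    for seed in range(seed0, seed0 + n_seeds):
        cfg = SimulationConfig(seed=seed)
        hits, truth = simulate_motif_landscape(ann, cfg)
        res = enrichment_test(
            hits, truth.enriched_gene_set[:100], gene_ids, n_perm=1000, seed=seed
        )
        if res.p_perm <= 0.001 and res.z > 3:
            n_pass += 1
    return {"fraction": n_pass / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# Golden demo run


def demo_config(seed=11, outdir="demo_run"):
    """The bundled end-to-end demo configuration (small but complete)."""
    from .pipeline import validate_config

    return validate_config(
        {
            "seed": seed,
            "outdir": outdir,
            "simulate": {"n_chroms": 2, "chrom_len": 300_000, "n_genes": 120, "n_tes": 50},
        }
    )


def golden_run(outdir, seed=11):
    """Run the demo pipeline and return its stage-output checksums."""
    from .pipeline import output_checksums, run_pipeline

    cfg = demo_config(seed=seed, outdir=str(outdir))
    run_pipeline(cfg)
    return output_checksums(outdir)
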