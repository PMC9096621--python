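"""Methylome analysis: context assignment, differential methylation, profiles.

The differential-methylation caller works on two pooled samples (the study
design pools biological replicates into one WGBS library per genotype/stage,
so there is no replicate variance to model). For a set of regions and one
context it applies, in order:

1. a Fisher's exact test per cytosine (coverage-filtered), BH-adjusted
   across all tested cytosines, giving differentially methylated cytosines
   (DMCs) at ``c_fdr`` with an optional minimum per-cytosine difference;
2. a region-level Fisher's exact test on counts pooled over the region's
   cytosines, BH-adjusted across regions;
3. a region is called hyper-/hypomethylated only when its region-level
   q-value passes ``region_fdr`` AND it contains at least ``min_dmc`` DMCs
   in the tested context — the conservative conjunction of the two
   plausible readings of an FDR rule plus a >= 10 DMC rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .core import CONTEXTS, GenomicInterval
from .stats import bh_adjust, fisher_exact_vec

_COMP = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Context assignment


def _fetch(genome, chrom, start, end):
    seq = genome[chrom]
    if not isinstance(seq, str):
        seq = str(seq[:])  # pyfaidx FastaRecord
    return seq[max(0, start) : end].upper()


def assign_context(genome, chrom, pos, strand):
    """Methylation context (CG / CHG / CHH) of the cytosine at (pos, strand).

    On the + strand the two downstream bases decide: CpG if the next base is
    G, CHG if the base after that is G, CHH otherwise (H = A, C or T). On the
    - strand the same rule applies to the reverse complement, i.e. the two
    upstream reference bases read leftwards. Cytosines too close to the
    chromosome end to see two downstream bases default to CHH.
    """
    if strand == "+":
        tri = _fetch(genome, chrom, pos, pos + 3)
        if not tri or tri[0] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {tri[:1] or '?'}, not C")
        if len(tri) > 1 and tri[1] == "G":
            return "CG"
        if len(tri) > 2 and tri[2] == "G":
            return "CHG"
        return "CHH"
    elif strand == "-":
        tri = _fetch(genome, chrom, pos - 2, pos + 1)
        # reverse-complement so the cytosine comes first, then apply + rule
        tri_rc = tri.translate(_COMP)[::-1]
        if not tri_rc or tri_rc[0] != "C":
            raise ValueError(f"{chrom}:{pos}(-) is not C on the - strand")
        if len(tri_rc) > 1 and tri_rc[1] == "G":
            return "CG"
        if len(tri_rc) > 2 and tri_rc[2] == "G":
            return "CHG"
        return "CHH"
    raise ValueError(f"invalid strand {strand!r}")


def cytosine_catalogue(seq: str) -> pd.DataFrame:
    """All cytosines on both strands of *seq* with their contexts (vectorized).

    Returns a DataFrame with columns pos, strand, context, sorted by
    position. A cytosine on the - strand is a G on the reference.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    n = arr.size

    def _contexts(pos, nxt, nxt2):
        ctx = np.full(pos.size, "CHH", dtype=object)
        ctx[nxt2] = "CHG"
        ctx[nxt] = "CG"
        return ctx

    # + strand: downstream bases
    pos_p = np.flatnonzero(is_c)
    nxt = np.zeros(pos_p.size, bool)
    nxt2 = np.zeros(pos_p.size, bool)
    ok1 = pos_p + 1 < n
    nxt[ok1] = is_g[pos_p[ok1] + 1]
    ok2 = pos_p + 2 < n
    nxt2[ok2] = is_g[pos_p[ok2] + 2]
    ctx_p = _contexts(pos_p, nxt, nxt2)

    # - strand: upstream reference bases, complemented (C on ref == G on -)
    pos_m = np.flatnonzero(is_g)
    nxt = np.zeros(pos_m.size, bool)
    nxt2 = np.zeros(pos_m.size, bool)
    ok1 = pos_m - 1 >= 0
    nxt[ok1] = is_c[pos_m[ok1] - 1]
    ok2 = pos_m - 2 >= 0
    nxt2[ok2] = is_c[pos_m[ok2] - 2]
    ctx_m = _contexts(pos_m, nxt, nxt2)

    df = pd.DataFrame(
        {
            "pos": np.concatenate([pos_p, pos_m]),
            "strand": ["+"] * pos_p.size + ["-"] * pos_m.size,
            "context": np.concatenate([ctx_p, ctx_m]),
        }
    )
    return df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Per-cytosine test


def test_cytosine(site_a, site_b):
    """Two-sided Fisher's exact test between two samples at one cytosine.

    Returns ``(p, diff)`` with diff = level_b - level_a.
    """
    if site_a.total == 0 or site_b.total == 0:
        raise ValueError("zero-coverage site: filter before testing")
    p = float(fisher_exact_vec(site_a.meth, site_a.total, site_b.meth, site_b.total)[0])
    return p, site_b.level - site_a.level


# ---------------------------------------------------------------------------
# Region-level calling


@dataclass
class DMCall:
    """Differential-methylation verdict for one region in one context."""

    region: GenomicInterval
    region_id: str
    context: str
    meth_level_a: float
    meth_level_b: float
    diff: float
    n_covered_c: int
    n_dmc: int
    p: float
    q: float
    status: str  # hyper / hypo / ns


def _region_site_indices(df, regions):
    """Per-region arrays of row indices of *df* falling inside the region.

    Regions may overlap (adjacent promoters often do); a cytosine inside two
    regions contributes to both, but is only ever tested once.
    """
    by_chrom: dict[str, np.ndarray] = {}
    order_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        by_chrom[chrom] = pos[order]
        order_by_chrom[chrom] = sub.index.to_numpy()[order]
    out = []
    for r in regions:
        pos = by_chrom.get(r.chrom)
        if pos is None:
            out.append(np.array([], dtype=np.int64))
            continue
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        out.append(order_by_chrom[r.chrom][lo:hi])
    return out


def call_region_dm(
    sites_a,
    sites_b,
    regions,
    context,
    min_coverage=10,
    c_fdr=0.05,
    region_fdr=0.05,
    min_dmc=10,
    min_diff_c=0.0,
):
    """Call differential methylation for *regions* in one context.

    *sites_a* / *sites_b* are per-sample cytosine DataFrames (columns chrom,
    pos, strand, context, meth, total) as returned by
    :func:`photoepi.io_formats.read_cytosine_report`. Only cytosines covered
    at >= *min_coverage* in BOTH samples are used. Returns a list of
    :class:`DMCall`, one per region, in input order.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    regions = list(regions)
    merged = pd.merge(
        sites_a,
        sites_b,
        on=["chrom", "pos", "strand", "context"],
        suffixes=("_a", "_b"),
    )
    merged = merged[
        (merged["context"] == context)
        & (merged["total_a"] >= min_coverage)
        & (merged["total_b"] >= min_coverage)
    ].reset_index(drop=True)

    site_idx = _region_site_indices(merged, regions)
    tested = np.zeros(len(merged), dtype=bool)
    for idx in site_idx:
        tested[idx] = True

    ma = merged["meth_a"].to_numpy()
    ta = merged["total_a"].to_numpy()
    mb = merged["meth_b"].to_numpy()
    tb = merged["total_b"].to_numpy()

    is_dmc = np.zeros(len(merged), dtype=bool)
    if tested.any():
        p_c = fisher_exact_vec(ma[tested], ta[tested], mb[tested], tb[tested])
        q_c = bh_adjust(p_c)
        diff_c = mb[tested] / tb[tested] - ma[tested] / ta[tested]
        is_dmc[tested] = (q_c < c_fdr) & (np.abs(diff_c) >= min_diff_c)

    # pooled per-region counts (a site inside two regions counts in both)
    n_regions = len(regions)
    sum_ma = np.zeros(n_regions)
    sum_ta = np.zeros(n_regions)
    sum_mb = np.zeros(n_regions)
    sum_tb = np.zeros(n_regions)
    n_cov = np.zeros(n_regions, dtype=int)
    n_dmc_arr = np.zeros(n_regions, dtype=int)
    for i, idx in enumerate(site_idx):
        if idx.size == 0:
            continue
        sum_ma[i] = ma[idx].sum()
        sum_ta[i] = ta[idx].sum()
        sum_mb[i] = mb[idx].sum()
        sum_tb[i] = tb[idx].sum()
        n_cov[i] = idx.size
        n_dmc_arr[i] = int(is_dmc[idx].sum())

    calls: list[DMCall] = []
    covered = n_cov > 0
    p_region = np.full(n_regions, np.nan)
    for i in np.flatnonzero(covered):
        table = [
            [int(sum_ma[i]), int(sum_ta[i] - sum_ma[i])],
            [int(sum_mb[i]), int(sum_tb[i] - sum_mb[i])],
        ]
        p_region[i] = _scipy_fisher(table)[1]
    q_region = np.full(n_regions, np.nan)
    if covered.any():
        q_region[covered] = bh_adjust(p_region[covered])

    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = np.where(covered, sum_ma / np.where(sum_ta > 0, sum_ta, 1), np.nan)
        level_b = np.where(covered, sum_mb / np.where(sum_tb > 0, sum_tb, 1), np.nan)
    diff = level_b - level_a

    for i, region in enumerate(regions):
        if not covered[i]:
            status = "ns"
        elif q_region[i] < region_fdr and n_dmc_arr[i] >= min_dmc and diff[i] != 0:
            status = "hyper" if diff[i] > 0 else "hypo"
        else:
            status = "ns"
        calls.append(
            DMCall(
                region=region,
                region_id=region.name or f"region_{i}",
                context=context,
                meth_level_a=float(level_a[i]),
                meth_level_b=float(level_b[i]),
                diff=float(diff[i]),
                n_covered_c=int(n_cov[i]),
                n_dmc=int(n_dmc_arr[i]),
                p=float(p_region[i]),
                q=float(q_region[i]),
                status=status,
            )
        )
    return calls


def dm_calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [c.region_id for c in calls],
            "chrom": [c.region.chrom for c in calls],
            "start": [c.region.start for c in calls],
            "end": [c.region.end for c in calls],
            "context": [c.context for c in calls],
            "meth_level_a": [c.meth_level_a for c in calls],
            "meth_level_b": [c.meth_level_b for c in calls],
            "diff": [c.diff for c in calls],
            "n_covered_c": [c.n_covered_c for c in calls],
            "n_dmc": [c.n_dmc for c in calls],
            "p": [c.p for c in calls],
            "q": [c.q for c in calls],
            "status": [c.status for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Promoters


def promoter_regions(genes, length=2000, chrom_lengths=None):
    """2-kb (by default) regions upstream of each gene's TSS.

    Strand-aware: upstream of the start for + genes, of the end for - genes;
    clipped at chromosome boundaries. Genes whose promoter would be empty
    (TSS at a chromosome edge) are skipped with a warning.
    """
    out = []
    for g in genes:
        if g.feature_class != "gene":
            continue
        iv = g.interval
        if iv.strand == "+":
            start, end = max(0, iv.start - length), iv.start
        else:
            limit = chrom_lengths.get(iv.chrom) if chrom_lengths else None
            start = iv.end
            end = iv.end + length if limit is None else min(limit, iv.end + length)
        if start >= end:
            warnings.warn(f"gene {g.gene_id}: empty promoter at chromosome edge, skipped")
            continue
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand, name=g.gene_id))
    return out


# ---------------------------------------------------------------------------
# Binned chromosome profiles


@dataclass
class BinProfile:
    chrom: str
    bin_start: int
    bin_size: int
    context: str
    sample: str
    meth_level: float
    diff_vs_ref: float
    status: str  # hypo / hyper / unchanged / (nan diff -> unchanged)
    density_genes: float
    density_tes: float
    n_sites: int


def _feature_density(models, chrom_lengths, bin_size, feature_class):
    """Nucleotides covered per million, per (chrom, bin)."""
    dens: dict[tuple[str, int], float] = {}
    for m in models:
        if m.feature_class != feature_class:
            continue
        iv = m.interval
        b0 = iv.start // bin_size
        b1 = (iv.end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo, hi = b * bin_size, (b + 1) * bin_size
            ov = min(iv.end, hi) - max(iv.start, lo)
            key = (iv.chrom, b * bin_size)
            dens[key] = dens.get(key, 0.0) + ov
    return {k: v / bin_size * 1e6 for k, v in dens.items()}


def bin_profile(
    sites_by_sample,
    chrom_lengths,
    annotation,
    ref_sample,
    bin_size=1_000_000,
    min_coverage=10,
    diff_threshold=0.05,
    as_frame=True,
):
    """1-Mb (by default) binned methylation levels and genotype differences.

    Only cytosines covered at >= *min_coverage* in ALL samples contribute, so
    every sample's level in a bin is computed over the same site set. Bins
    tile each chromosome; the last bin may be short. A bin level is the
    pooled ``sum(meth)/sum(total)``; a bin with no common covered cytosines
    gets NaN (undefined, not zero). The difference of each sample against
    *ref_sample* is classified hypomethylated below ``-diff_threshold``,
    hypermethylated above ``+diff_threshold``, else unchanged.
    """
    names = list(sites_by_sample)
    if ref_sample not in names:
        raise ValueError(f"reference sample {ref_sample!r} not among samples")
    common = None
    for name in names:
        df = sites_by_sample[name]
        df = df[df["total"] >= min_coverage]
        df = df[["chrom", "pos", "strand", "context", "meth", "total"]].rename(
            columns={"meth": f"meth_{name}", "total": f"total_{name}"}
        )
        common = df if common is None else pd.merge(
            common, df, on=["chrom", "pos", "strand", "context"]
        )
    common = common.reset_index(drop=True)
    common["bin_start"] = (common["pos"] // bin_size) * bin_size

    gene_dens = _feature_density(annotation, chrom_lengths, bin_size, "gene")
    te_dens = _feature_density(annotation, chrom_lengths, bin_size, "TE")

    grouped = common.groupby(["chrom", "bin_start", "context"], sort=True)
    agg = grouped[
        [f"meth_{n}" for n in names] + [f"total_{n}" for n in names]
    ].sum()
    counts = grouped.size()

    profiles: list[BinProfile] = []
    for chrom, clen in chrom_lengths.items():
        for bin_start in range(0, clen, bin_size):
            for ctx in CONTEXTS:
                key = (chrom, bin_start, ctx)
                dg = gene_dens.get((chrom, bin_start), 0.0)
                dt = te_dens.get((chrom, bin_start), 0.0)
                if key in agg.index:
                    row = agg.loc[key]
                    n_sites = int(counts.loc[key])
                    levels = {
                        n: row[f"meth_{n}"] / row[f"total_{n}"] if row[f"total_{n}"] else np.nan
                        for n in names
                    }
                else:
                    n_sites = 0
                    levels = {n: np.nan for n in names}
                for n in names:
                    diff = levels[n] - levels[ref_sample] if n != ref_sample else np.nan
                    if n == ref_sample or np.isnan(diff):
                        status = "unchanged"
                    elif diff < -diff_threshold:
                        status = "hypo"
                    elif diff > diff_threshold:
                        status = "hyper"
                    else:
                        status = "unchanged"
                    profiles.append(
                        BinProfile(
                            chrom=chrom,
                            bin_start=bin_start,
                            bin_size=min(bin_size, clen - bin_start),
                            context=ctx,
                            sample=n,
                            meth_level=float(levels[n]),
                            diff_vs_ref=float(diff) if n != ref_sample else np.nan,
                            status=status,
                            density_genes=dg,
                            density_tes=dt,
                            n_sites=n_sites,
                        )
                    )
    if not as_frame:
        return profiles
    return pd.DataFrame([vars(p) for p in profiles])
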