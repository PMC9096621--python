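"""De novo sRNA cluster calling, categorization, and methylation linkage.

Cluster calling is a deliberate simplification of aligner-integrated tools
(ShortStack et al.): size-selected reads (18-24 nt by default) from all
samples are pooled, overlapping or near-adjacent reads are merged into
coverage islands (gap <= ``pad``), and islands with too few supporting reads
are dropped. Clusters are defined on the sample union so every sample has a
count for every cluster, as the downstream differential test requires.

A cluster's genomic category follows the precedence
gene_body > promoter > TE > intergenic (>= 1 bp overlap; ties broken by the
largest overlap), so the four categories partition the cluster set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval
from .methylome import call_region_dm

CATEGORIES = ("gene_body", "promoter", "TE", "intergenic")

READ_COLUMNS = ["chrom", "start", "end", "length"]


@dataclass
class SRNACluster:
    cluster_id: str
    interval: GenomicInterval
    category: str | None = None
    linked_gene: str | None = None
    read_count_per_sample: dict = field(default_factory=dict)


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        df = reads.copy()
    else:
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, len(iv)) for iv in reads],
            columns=READ_COLUMNS,
        )
    if "length" not in df.columns:
        df["length"] = df["end"] - df["start"]
    return df[READ_COLUMNS]


def call_clusters(reads_by_sample, min_len=18, max_len=24, pad=75, min_reads=3):
    """Merge size-selected reads from all samples into sRNA clusters.

    *reads_by_sample* maps sample name -> DataFrame (chrom, start, end,
    length) or list of intervals. Reads outside [min_len, max_len] are
    discarded; retained reads are pooled, merged into islands joined across
    gaps <= *pad* bp, and islands supported by fewer than *min_reads* pooled
    reads are dropped. Returns a list of :class:`SRNACluster` with
    per-sample read counts (>= 1 bp overlap with the cluster interval).
    """
    samples = list(reads_by_sample)
    frames = {}
    for s in samples:
        df = _reads_frame(reads_by_sample[s])
        df = df[(df["length"] >= min_len) & (df["length"] <= max_len)]
        frames[s] = df
    for s, df in frames.items():
        starts = df["start"].to_numpy()
        chroms = df["chrom"].to_numpy()
        same = chroms[1:] == chroms[:-1]
        if (same & (starts[1:] < starts[:-1])).any():
            warnings.warn(f"sample {s}: sRNA reads not position-sorted; sorting internally")
    pooled = (
        pd.concat(frames.values(), ignore_index=True)
        if frames
        else pd.DataFrame(columns=READ_COLUMNS)
    )
    clusters: list[SRNACluster] = []
    if len(pooled) == 0:
        return clusters
    pooled = pooled.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    n_cluster = 0
    for chrom, sub in pooled.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # merge sorted reads into islands with gap <= pad
        run_end = np.maximum.accumulate(ends)
        breaks = np.flatnonzero(starts[1:] > run_end[:-1] + pad) + 1
        bounds = np.concatenate([[0], breaks, [len(sub)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n_support = hi - lo
            if n_support < min_reads:
                continue
            iv = GenomicInterval(chrom, int(starts[lo]), int(run_end[hi - 1]))
            counts = {}
            for s in samples:
                sdf = frames[s]
                sdf_c = sdf[sdf["chrom"] == chrom]
                counts[s] = int(
                    ((sdf_c["start"] < iv.end) & (sdf_c["end"] > iv.start)).sum()
                )
            n_cluster += 1
            clusters.append(
                SRNACluster(
                    cluster_id=f"SRC{n_cluster:05d}",
                    interval=GenomicInterval(iv.chrom, iv.start, iv.end, name=f"SRC{n_cluster:05d}"),
                    read_count_per_sample=counts,
                )
            )
    # renumber in (chrom, start) order for stable ids
    for i, c in enumerate(sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start)), 1):
        cid = f"SRC{i:05d}"
        c.cluster_id = cid
        c.interval = GenomicInterval(
            c.interval.chrom, c.interval.start, c.interval.end, name=cid
        )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return clusters


def _best_overlap(interval, features):
    """(feature, overlap) with the largest >=1 bp overlap, else (None, 0)."""
    best, best_ov = None, 0
    for f in features:
        iv = f.interval if hasattr(f, "interval") else f
        ov = interval.overlap(iv)
        if ov > best_ov:
            best, best_ov = f, ov
    return best, best_ov


def categorize_cluster(cluster, genes, promoters, tes):
    """Assign the cluster's genomic category and linked gene (in place).

    Precedence gene_body > promoter > TE > intergenic; the linked gene is
    the one whose body (or promoter) overlaps the cluster most.
    """
    iv = cluster.interval
    gene, ov = _best_overlap(iv, genes)
    if ov > 0:
        cluster.category, cluster.linked_gene = "gene_body", gene.gene_id
        return cluster
    prom, ov = _best_overlap(iv, promoters)
    if ov > 0:
        cluster.category, cluster.linked_gene = "promoter", prom.name
        return cluster
    te, ov = _best_overlap(iv, tes)
    if ov > 0:
        cluster.category, cluster.linked_gene = "TE", None
        return cluster
    cluster.category, cluster.linked_gene = "intergenic", None
    return cluster


def categorize_clusters(clusters, annotation, promoters):
    """Categorize every cluster against an annotation (genes + TEs)."""
    genes = [m for m in annotation if m.feature_class == "gene"]
    tes = [m for m in annotation if m.feature_class == "TE"]
    # bucket features per chromosome to keep the scan linear-ish
    gidx, pidx, tidx = _chrom_index(genes), _chrom_index(promoters), _chrom_index(tes)
    for c in clusters:
        chrom = c.interval.chrom
        categorize_cluster(c, gidx.get(chrom, ()), pidx.get(chrom, ()), tidx.get(chrom, ()))
    return clusters


def _chrom_index(features):
    out: dict[str, list] = {}
    for f in features:
        iv = f.interval if hasattr(f, "interval") else f
        out.setdefault(iv.chrom, []).append(f)
    return out


def clusters_to_count_matrix(clusters, lib_sizes=None) -> CountMatrix:
    """Per-sample read counts of all clusters as a CountMatrix.

    Library sizes default to total cluster-assigned reads per sample; pass
    explicit totals (e.g. all aligned reads) to override.
    """
    if not clusters:
        raise ValueError("no clusters")
    samples = list(clusters[0].read_count_per_sample)
    counts = np.array(
        [[c.read_count_per_sample[s] for s in samples] for c in clusters], dtype=np.int64
    )
    return CountMatrix([c.cluster_id for c in clusters], samples, counts, lib_sizes)


def sctgr_methylation(
    clusters,
    sites_a,
    sites_b,
    contexts=("CG", "CHG", "CHH"),
    min_abs_diff=0.05,
    **dm_kwargs,
):
    """Methylation calls for sRNA cluster-targeted genome regions (sCTGRs).

    Delegates to :func:`photoepi.methylome.call_region_dm` with the cluster
    intervals as regions, once per context. Returns a DataFrame with one row
    per (cluster, context) carrying the DMCall columns plus
    ``meets_min_diff`` — whether the pooled |difference| reaches
    *min_abs_diff* (the 5% floor used when associating sCTGR methylation
    with sRNA accumulation).
    """
    from .methylome import dm_calls_to_frame

    regions = [c.interval for c in clusters]
    frames = []
    for ctx in contexts:
        calls = call_region_dm(sites_a, sites_b, regions, ctx, **dm_kwargs)
        df = dm_calls_to_frame(calls)
        df["meets_min_diff"] = np.abs(df["diff"].to_numpy()) >= min_abs_diff
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.loc[out["n_covered_c"] == 0, "meets_min_diff"] = False
    return out


def clusters_to_frame(clusters) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "chrom": [c.interval.chrom for c in clusters],
            "start": [c.interval.start for c in clusters],
            "end": [c.interval.end for c in clusters],
            "category": [c.category for c in clusters],
            "linked_gene": [c.linked_gene for c in clusters],
            **{
                f"reads_{s}": [c.read_count_per_sample.get(s, 0) for c in clusters]
                for s in (clusters[0].read_count_per_sample if clusters else {})
            },
        }
    )
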