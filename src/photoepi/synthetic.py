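"""Synthetic miniature study generator with planted ground truth.

Generates every input the pipeline consumes — a small multi-chromosome
genome with gene-rich arms and a TE-rich pericentromere, per-sample
cytosine reports, NB count matrices, sRNA read alignments, and positional
motif-occurrence landscapes — with the effects planted where the ground
truth says they are, so each downstream stage can be tested for parameter
recovery and type-I calibration without any external data.

Default study conditions (overridable via :class:`SimulationConfig`):

* genome GC content 0.36 (tomato-like); genes placed in the outer thirds of
  each chromosome, TEs in the middle third;
* context mean methylation CG 0.80, CHG 0.67, CHH 0.23; beta-binomial
  counts (overdispersion 0.05) at Poisson(20) coverage, one pooled sample
  per group (the study's pooled WGBS design);
* NB counts with dispersion 0.05, three replicates per group, planted
  differential features at |log2FC| = 2;
* planted differentially methylated regions at |delta| = 0.3 on promoters;
* motif landscapes with uniform background occurrences over 20 kb upstream
  and TSS-proximal extra occurrences (probability 0.6 within 1 kb) for the
  enriched gene set.

Every generator draws from ``default_rng([seed, salt])`` with a
function-specific salt, so outputs are byte-identical across runs and
independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix, GeneModel, GenomicInterval
from .methylome import cytosine_catalogue, promoter_regions
from .motifs import MotifHit

_SALTS = {"genome": 1, "methylome": 2, "counts": 3, "srna": 4, "motif": 5}


@dataclass
class SimulationConfig:
    """All knobs of the miniature study; deterministic given ``seed``."""

    # genome / annotation
    n_chroms: int = 2
    chrom_len: int = 500_000
    n_genes: int = 200
    n_tes: int = 80
    gc_content: float = 0.36
    gene_len_range: tuple = (1_000, 3_000)
    te_len_range: tuple = (1_500, 4_000)
    # methylome
    context_means: dict = field(
        default_factory=lambda: {"CG": 0.80, "CHG": 0.67, "CHH": 0.23}
    )
    dmr_fraction: float = 0.1
    dmr_delta: float = 0.3
    dmr_context: str = "CHH"
    coverage_mean: float = 20.0
    overdispersion: float = 0.05
    n_meth_samples_per_group: int = 1  # pooled WGBS design
    # counts
    n_samples_per_group: int = 3
    n_features: int = 2_000
    deg_fraction: float = 0.1
    deg_lfc: float = 2.0
    nb_dispersion: float = 0.05
    base_depth: float = 2e6
    lib_size_sigma: float = 0.15
    # sRNA reads
    n_srna_loci: int = 150
    srna_locus_len_range: tuple = (100, 400)
    srna_read_rate: float = 20.0
    diff_cluster_fraction: float = 0.1
    diff_cluster_lfc: float = 2.0
    # motif landscape
    motif_window: int = 20_000
    motif_background_rate: float = 2.0
    motif_enriched_fraction: float = 0.5
    motif_tss_window: int = 1_000
    motif_p_extra: float = 0.6
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        for name in ("dmr_fraction", "deg_fraction", "diff_cluster_fraction",
                     "motif_enriched_fraction", "motif_p_extra"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for ctx, m in self.context_means.items():
            if not 0.0 < m < 1.0:
                raise ValueError(f"context mean {ctx}={m} outside (0, 1)")
        if self.coverage_mean <= 0 or self.overdispersion <= 0 or self.nb_dispersion <= 0:
            raise ValueError("coverage/overdispersion/dispersion must be positive")
        if not -1.0 <= self.dmr_delta <= 1.0:
            raise ValueError("dmr_delta outside [-1, 1]")
        if self.motif_tss_window > self.motif_window:
            raise ValueError("motif_tss_window exceeds the scanned window")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SALTS[stage]])


@dataclass
class GroundTruth:
    """Planted effects, recoverable by the downstream modules."""

    dmr_regions: list = field(default_factory=list)  # (interval, context, delta)
    deg_lfc: dict = field(default_factory=dict)  # feature id -> signed log2 fc
    enriched_gene_set: list = field(default_factory=list)
    diff_cluster_lfc: dict = field(default_factory=dict)
    srna_loci: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome and annotation


def _place_features(rng, capacity_start, capacity_end, lengths):
    """Non-overlapping intervals of the given lengths inside [start, end)."""
    total = int(np.sum(lengths))
    free = (capacity_end - capacity_start) - total
    if free < 0:
        raise ValueError(
            f"features ({total} bp) exceed capacity {capacity_end - capacity_start} bp"
        )
    k = len(lengths)
    gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    out = []
    cursor = capacity_start
    for i, length in enumerate(lengths):
        cursor += int(gaps[i])
        out.append((cursor, cursor + int(length)))
        cursor += int(length)
    return out


def simulate_genome(config: SimulationConfig):
    """Random genome plus annotation: genes on the arms, TEs in the middle.

    Returns ``(sequences, annotation)`` with *sequences* a chrom -> string
    dict and *annotation* a list of :class:`GeneModel` (genes stranded, TEs
    unstranded) sorted by position.
    """
    rng = config.rng("genome")
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    sequences = {}
    annotation: list[GeneModel] = []
    genes_per_chrom = _split_evenly(config.n_genes, config.n_chroms)
    tes_per_chrom = _split_evenly(config.n_tes, config.n_chroms)
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = "".join(rng.choice(bases, size=config.chrom_len, p=probs))
        sequences[chrom] = seq
        third = config.chrom_len // 3
        n_g = genes_per_chrom[ci]
        n_left = n_g // 2
        lengths = rng.integers(*config.gene_len_range, size=n_g)
        placements = _place_features(rng, 0, third, lengths[:n_left]) + _place_features(
            rng, 2 * third, config.chrom_len, lengths[n_left:]
        )
        for gi, (s, e) in enumerate(placements):
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{chrom}_{gi + 1:04d}"
            annotation.append(
                GeneModel(gid, GenomicInterval(chrom, s, e, strand, name=gid), "gene")
            )
        te_lengths = rng.integers(*config.te_len_range, size=tes_per_chrom[ci])
        for ti, (s, e) in enumerate(_place_features(rng, third, 2 * third, te_lengths)):
            tid = f"te_{chrom}_{ti + 1:04d}"
            annotation.append(
                GeneModel(tid, GenomicInterval(chrom, s, e, ".", name=tid), "TE")
            )
    annotation.sort(key=lambda m: (m.interval.chrom, m.interval.start))
    return sequences, annotation


def _split_evenly(n, k):
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# Methylomes


def simulate_methylomes(sequences, annotation, config: SimulationConfig, dmr_gene_ids=None):
    """Beta-binomial cytosine reports for two groups with planted DMRs.

    DMRs are planted on a random subset of gene promoters (2 kb upstream),
    in ``config.dmr_context``, with a per-region random sign on
    ``config.dmr_delta``; the mutant-group mean is shifted and clipped to
    [0.01, 0.99]. Pass *dmr_gene_ids* to plant the DMRs on specific genes'
    promoters instead (e.g. to couple methylation changes to planted DEGs).
    Group names are ``WT`` and ``mut`` (suffixed _1, _2 ... if more than one
    sample per group). Sites with zero simulated coverage are absent from
    the reports, as they would be from a real sequencer.

    Returns ``(reports, truth)`` with *reports* mapping sample name -> site
    DataFrame and *truth* carrying the planted (interval, context, delta).
    """
    rng = config.rng("methylome")
    chrom_lengths = {c: len(s) for c, s in sequences.items()}
    genes = [m for m in annotation if m.feature_class == "gene"]
    promoters = promoter_regions(genes, 2000, chrom_lengths)
    if dmr_gene_ids is not None:
        wanted = set(dmr_gene_ids)
        dmr_idx = [i for i, p in enumerate(promoters) if p.name in wanted]
    else:
        n_dmr = int(round(config.dmr_fraction * len(promoters)))
        dmr_idx = rng.choice(len(promoters), size=n_dmr, replace=False) if n_dmr else []
    truth = GroundTruth()
    for i in dmr_idx:
        delta = float(config.dmr_delta) * (1 if rng.random() < 0.5 else -1)
        truth.dmr_regions.append((promoters[i], config.dmr_context, delta))

    # per-chromosome cytosine catalogue and per-site group means
    frames = []
    for chrom, seq in sequences.items():
        cat = cytosine_catalogue(seq)
        cat.insert(0, "chrom", chrom)
        frames.append(cat)
    sites = pd.concat(frames, ignore_index=True)
    base_mean = sites["context"].map(config.context_means).to_numpy(dtype=float)
    mut_mean = base_mean.copy()
    for (region, ctx, delta) in truth.dmr_regions:
        mask = (
            (sites["chrom"] == region.chrom).to_numpy()
            & (sites["pos"].to_numpy() >= region.start)
            & (sites["pos"].to_numpy() < region.end)
            & (sites["context"] == ctx).to_numpy()
        )
        mut_mean[mask] = base_mean[mask] + delta
    mut_mean = np.clip(mut_mean, 0.01, 0.99)

    rho = config.overdispersion
    reports = {}
    for group, means in (("WT", base_mean), ("mut", mut_mean)):
        for si in range(config.n_meth_samples_per_group):
            name = group if config.n_meth_samples_per_group == 1 else f"{group}_{si + 1}"
            total = rng.poisson(config.coverage_mean, size=len(sites))
            a = means * (1 - rho) / rho
            b = (1 - means) * (1 - rho) / rho
            p_site = rng.beta(a, b)
            meth = rng.binomial(total, p_site)
            df = sites.copy()
            df["meth"] = meth
            df["total"] = total
            reports[name] = df[df["total"] > 0].reset_index(drop=True)[
                ["chrom", "pos", "strand", "context", "meth", "total"]
            ]
    return reports, truth


# ---------------------------------------------------------------------------
# Count matrices


def simulate_counts(
    annotation, config: SimulationConfig, kind="gene", feature_ids=None, planted=None
):
    """NB count matrix for two groups of replicates with planted DEGs.

    Features default to the annotation's genes for ``kind="gene"``; pass
    *feature_ids* (or leave annotation None to get ``config.n_features``
    generic features) for standalone matrices. Group B means of planted
    features are multiplied by 2**(+-deg_lfc); library sizes are log-normal
    around ``base_depth``. Pass *planted* (feature id -> signed log2 fold
    change) to control exactly which features change and how — used to
    couple expression changes to other planted effects.

    Returns ``(CountMatrix, truth)`` with the planted signed log2 fold
    changes in ``truth.deg_lfc`` (``diff_cluster_lfc`` for sRNA clusters).
    """
    rng = config.rng("counts")
    if feature_ids is None:
        if annotation is not None and kind == "gene":
            feature_ids = [m.gene_id for m in annotation if m.feature_class == "gene"]
        else:
            prefix = "feat" if kind == "gene" else "cluster"
            feature_ids = [f"{prefix}_{i + 1:05d}" for i in range(config.n_features)]
    n_feat = len(feature_ids)
    n_per = config.n_samples_per_group
    samples = [f"WT_{i + 1}" for i in range(n_per)] + [f"mut_{i + 1}" for i in range(n_per)]
    group_b = np.array([False] * n_per + [True] * n_per)

    base_cpm = rng.lognormal(mean=np.log(30.0), sigma=1.2, size=n_feat)
    lfc = np.zeros(n_feat)
    if planted is not None:
        index = {f: i for i, f in enumerate(feature_ids)}
        de_idx = np.array([index[f] for f in planted], dtype=int)
        lfc[de_idx] = [float(v) for v in planted.values()]
    else:
        frac = config.deg_fraction if kind == "gene" else config.diff_cluster_fraction
        lfc_mag = config.deg_lfc if kind == "gene" else config.diff_cluster_lfc
        n_de = int(round(frac * n_feat))
        de_idx = rng.choice(n_feat, size=n_de, replace=False) if n_de else np.array([], int)
        signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        lfc[de_idx] = signs * lfc_mag

    lib_sizes = config.base_depth * rng.lognormal(0.0, config.lib_size_sigma, size=len(samples))
    mean_cpm = base_cpm[:, None] * np.where(group_b[None, :], 2.0 ** lfc[:, None], 1.0)
    mu = mean_cpm * lib_sizes[None, :] / 1e6
    phi = config.nb_dispersion
    counts = rng.negative_binomial(n=1.0 / phi, p=1.0 / (1.0 + phi * mu))

    truth = GroundTruth()
    planted = {feature_ids[i]: float(lfc[i]) for i in de_idx}
    if kind == "gene":
        truth.deg_lfc = planted
    else:
        truth.diff_cluster_lfc = planted
    return CountMatrix(feature_ids, samples, counts, lib_sizes), truth


# ---------------------------------------------------------------------------
# sRNA reads


def simulate_srna_reads(sequences, annotation, config: SimulationConfig, coupled_loci=None):
    """Aligned 18-24 nt sRNA reads concentrated at discrete loci.

    Loci are placed in gene bodies, promoters, TEs and intergenic space
    (roughly 30/30/25/15%); each locus has a log-normal base abundance and a
    planted subset gets a 2**(+-diff_cluster_lfc) group-B multiplier. Reads
    are drawn per sample (NB around the locus rate), with lengths 18-24 and
    uniform placement within the locus. *coupled_loci*, a list of
    ``(GenomicInterval, signed_lfc)``, appends extra differential loci at
    chosen positions — the hook for coupling sRNA changes to planted
    methylation or expression effects.

    Returns ``(reads_by_sample, truth)``; truth records the loci and the
    planted per-locus signed log2 fold changes keyed by locus id.
    """
    rng = config.rng("srna")
    chrom_lengths = {c: len(s) for c, s in sequences.items()}
    genes = [m for m in annotation if m.feature_class == "gene"]
    tes = [m for m in annotation if m.feature_class == "TE"]
    promoters = promoter_regions(genes, 2000, chrom_lengths)

    loci = []
    placed: dict[str, list[tuple[int, int]]] = {}
    kinds = rng.choice(
        ["gene_body", "promoter", "TE", "intergenic"],
        size=config.n_srna_loci,
        p=[0.30, 0.30, 0.25, 0.15],
    )
    for i, kind in enumerate(kinds):
        # rejection-sample a non-overlapping placement (loci must be
        # disjoint so each maps to a distinct downstream cluster)
        for _attempt in range(60):
            length = int(rng.integers(*config.srna_locus_len_range))
            if kind == "gene_body" and genes:
                host = genes[rng.integers(len(genes))].interval
            elif kind == "promoter" and promoters:
                host = promoters[rng.integers(len(promoters))]
            elif kind == "TE" and tes:
                host = tes[rng.integers(len(tes))].interval
            else:
                chrom = f"chr{rng.integers(config.n_chroms) + 1}"
                third = chrom_lengths[chrom] // 3
                start = int(rng.integers(third, 2 * third - length))
                host = GenomicInterval(chrom, start, start + length + 1)
            length = min(length, len(host) - 1) or 1
            start = int(rng.integers(host.start, max(host.start + 1, host.end - length)))
            end = start + length
            # keep a >150 bp margin so merged clusters stay distinct
            occupied = placed.setdefault(host.chrom, [])
            if all(start >= e + 150 or end <= s - 150 for s, e in occupied):
                occupied.append((start, end))
                loci.append(
                    GenomicInterval(host.chrom, start, end, name=f"locus_{i + 1:04d}")
                )
                break

    n_diff = int(round(config.diff_cluster_fraction * len(loci)))
    diff_idx = list(rng.choice(len(loci), size=n_diff, replace=False)) if n_diff else []
    lfc = np.zeros(len(loci))
    lfc[diff_idx] = np.where(rng.random(n_diff) < 0.5, 1.0, -1.0) * config.diff_cluster_lfc
    if coupled_loci:
        for j, (iv, signed_lfc) in enumerate(coupled_loci):
            name = iv.name or f"coupled_{j + 1:04d}"
            diff_idx.append(len(loci))
            loci.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=name))
            lfc = np.append(lfc, float(signed_lfc))
    rates = rng.lognormal(np.log(config.srna_read_rate), 0.7, size=len(loci))

    n_per = config.n_samples_per_group
    samples = [f"WT_{i + 1}" for i in range(n_per)] + [f"mut_{i + 1}" for i in range(n_per)]
    group_b = [False] * n_per + [True] * n_per
    phi = config.nb_dispersion
    read_lengths = np.arange(18, 25)
    length_probs = np.array([0.05, 0.05, 0.08, 0.22, 0.15, 0.10, 0.35])  # 21/24-nt biased

    reads_by_sample = {}
    for sample, is_b in zip(samples, group_b):
        rows = []
        for li, locus in enumerate(loci):
            mu = rates[li] * (2.0 ** lfc[li] if is_b else 1.0)
            n_reads = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
            if n_reads == 0:
                continue
            lens = rng.choice(read_lengths, size=n_reads, p=length_probs)
            max_start = np.maximum(locus.start + 1, locus.end - lens)
            starts = rng.integers(locus.start, max_start)
            for s, ln in zip(starts, lens):
                rows.append((locus.chrom, int(s), int(s + ln), int(ln)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])
        reads_by_sample[sample] = df.sort_values(
            ["chrom", "start"], kind="mergesort"
        ).reset_index(drop=True)

    truth = GroundTruth()
    truth.srna_loci = loci
    truth.diff_cluster_lfc = {
        loci[i].name: float(lfc[i]) for i in diff_idx
    }
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# Motif landscapes


def simulate_motif_landscape(annotation, config: SimulationConfig, motif_id="synthetic_motif"):
    """Planted positional motif-occurrence landscape over gene promoters.

    Background occurrences fall uniformly over the 20-kb upstream window at
    rate ``motif_background_rate`` per gene; genes in the enriched set get
    one extra TSS-proximal occurrence (within ``motif_tss_window``) with
    probability ``motif_p_extra``.

    Returns ``(hits, truth)`` with *hits* a list of
    :class:`~photoepi.motifs.MotifHit`.
    """
    rng = config.rng("motif")
    gene_ids = [m.gene_id for m in annotation if m.feature_class == "gene"]
    n_enriched = int(round(config.motif_enriched_fraction * len(gene_ids)))
    enriched = set(
        rng.choice(gene_ids, size=n_enriched, replace=False).tolist() if n_enriched else []
    )
    hits: list[MotifHit] = []
    for g in gene_ids:
        n_bg = rng.poisson(config.motif_background_rate)
        for d in rng.integers(0, config.motif_window, size=n_bg):
            hits.append(MotifHit(g, int(d), "+", 0.0, 1e-5))
        if g in enriched and rng.random() < config.motif_p_extra:
            d = int(rng.integers(0, config.motif_tss_window))
            hits.append(MotifHit(g, d, "+", 0.0, 1e-5))
    truth = GroundTruth()
    truth.enriched_gene_set = sorted(enriched)
    return hits, truth


# ---------------------------------------------------------------------------
# Demo PFM (for end-to-end sequence scanning)


def make_demo_pfm(motif_id="DEMO_PIF", seed=0):
    """A strongly informative 10-column PFM around a PIF-type E-box core.

    Ten near-consensus columns keep the exact null tail below the 1e-5 scan
    threshold (an 8-mer cannot get below 0.25**8 ~ 1.5e-5 under a uniform
    background).
    """
    from .core import PFM

    consensus = "CACGTGGGCA"
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 97.0
    return PFM(motif_id, counts)
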