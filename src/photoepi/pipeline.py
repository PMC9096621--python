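"""Pipeline orchestration: one YAML config drives every stage.

Stages couple only through files on disk (each stage reads the previous
stage's TSV/BED/JSON outputs), so any stage can be re-run or tested in
isolation. A run writes a manifest recording the configuration, input
checksums, seed and package version; re-running an identical config and
seed reproduces every stage output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GenomicInterval
from .diffcounts import cpm_filter, nb_test, results_to_frame
from .integration import (
    gb_vs_promoter_srna,
    overlap_deg_dmp,
    srna_methylation_association,
)
from .io_formats import (
    read_bed,
    read_count_matrix,
    read_cytosine_report,
    read_fasta,
    read_gff3,
    read_jaspar_pfm,
    write_bed,
    write_count_matrix,
    write_cytosine_report,
    write_fasta,
    write_gff3,
    write_jaspar_pfm,
)
from .methylome import DMCall, call_region_dm, dm_calls_to_frame, promoter_regions
from .motifs import PWM, enrichment_test, pwm_scan, upstream_regions
from .srna import (
    call_clusters,
    categorize_clusters,
    clusters_to_count_matrix,
    clusters_to_frame,
    sctgr_methylation,
)
from .synthetic import (
    SimulationConfig,
    make_demo_pfm,
    simulate_counts,
    simulate_genome,
    simulate_methylomes,
    simulate_srna_reads,
)

log = logging.getLogger("photoepi")

_STAGE_DEFAULTS = {
    "dm": dict(min_coverage=10, c_fdr=0.05, region_fdr=0.05, min_dmc=10,
               min_diff_c=0.0, promoter_length=2000),
    "de": dict(fdr=0.05, min_cpm=2.0, shrink=1.0),
    "clusters": dict(min_len=18, max_len=24, pad=75, min_reads=3,
                     fdr=0.05, min_cpm=2.0),
    "motif": dict(window=20000, step=100, n_perm=1000, p_threshold=1e-5,
                  reduction="max"),
    "integrate": dict(min_diff=0.05, min_fraction=0.02),
}
_TOP_KEYS = {"seed", "outdir", "simulate"} | set(_STAGE_DEFAULTS)


class ConfigError(ValueError):
    """The run configuration failed validation."""


def load_config(path):
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw):
    """Strict schema check: unknown keys anywhere are rejected."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {"seed": int(raw.get("seed", 0)), "outdir": raw.get("outdir", "photoepi_run")}
    sim = raw.get("simulate", {})
    sim_fields = set(SimulationConfig.__dataclass_fields__)
    unknown = set(sim) - sim_fields
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    cfg["simulate"] = sim
    for stage, defaults in _STAGE_DEFAULTS.items():
        block = raw.get(stage, {})
        unknown = set(block) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown {stage} keys: {sorted(unknown)}")
        cfg[stage] = {**defaults, **block}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, outdir=None):
    """Run simulate -> dm / de / clusters -> motif-enrich -> integrate.

    *config* is a validated config dict (see :func:`validate_config`).
    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config["seed"], "stages": {}, "config": config}

    sim_kwargs = dict(config["simulate"])
    sim_kwargs["seed"] = config["seed"]
    sim = SimulationConfig(**sim_kwargs)

    # ---- simulate -----------------------------------------------------
    log.info("stage simulate: genome + methylomes + counts + sRNA reads")
    seqs, ann = simulate_genome(sim)
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    write_fasta(seqs, out / "genome.fa")
    write_gff3(ann, out / "annotation.gff3")
    reports, meth_truth = simulate_methylomes(seqs, ann, sim)
    for name, df in reports.items():
        write_cytosine_report(df, out / f"cytosines_{name}.tsv")
    counts, count_truth = simulate_counts(ann, sim, kind="gene")
    write_count_matrix(counts, out / "gene_counts.tsv")
    # RdDM-like coupling: each planted DMR also hosts a differential sRNA
    # locus whose direction follows the methylation change
    coupled = []
    for i, (iv, _ctx, delta) in enumerate(meth_truth.dmr_regions):
        mid = (iv.start + iv.end) // 2
        coupled.append(
            (GenomicInterval(iv.chrom, mid - 150, mid + 150, name=f"rddm_{i + 1:03d}"),
             sim.diff_cluster_lfc * (1.0 if delta > 0 else -1.0))
        )
    reads, srna_truth = simulate_srna_reads(seqs, ann, sim, coupled_loci=coupled)
    for name, df in reads.items():
        ivs = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(int(r.length)))
            for r in df.itertuples()
        ]
        write_bed(ivs, out / f"srna_reads_{name}.bed")
    write_jaspar_pfm([make_demo_pfm()], out / "motif.pfm")
    _record(manifest, out, "simulate",
            [f"cytosines_{n}.tsv" for n in reports]
            + [f"srna_reads_{n}.bed" for n in reads]
            + ["genome.fa", "annotation.gff3", "gene_counts.tsv", "motif.pfm"])

    # ---- dm -----------------------------------------------------------
    log.info("stage dm: promoter differential methylation")
    prm = config["dm"]
    ann_r = read_gff3(out / "annotation.gff3")
    genes = [m for m in ann_r if m.feature_class == "gene"]
    meth_names = sorted(reports)
    sites = {
        n: read_cytosine_report(out / f"cytosines_{n}.tsv", min_total=prm["min_coverage"])
        for n in meth_names
    }
    sample_a = "WT" if "WT" in sites else meth_names[0]
    sample_b = next(n for n in meth_names if n != sample_a)
    promoters = promoter_regions(genes, prm["promoter_length"], chrom_lengths)
    frames = []
    for ctx in ("CG", "CHG", "CHH"):
        calls = call_region_dm(
            sites[sample_a], sites[sample_b], promoters, ctx,
            min_coverage=prm["min_coverage"], c_fdr=prm["c_fdr"],
            region_fdr=prm["region_fdr"], min_dmc=prm["min_dmc"],
            min_diff_c=prm["min_diff_c"],
        )
        frames.append(dm_calls_to_frame(calls))
    dm_df = pd.concat(frames, ignore_index=True)
    dm_df.to_csv(out / "dm_promoters.tsv", sep="\t", index=False)
    sig = dm_df[dm_df["status"] != "ns"]
    write_bed(
        [
            GenomicInterval(r.chrom, r.start, r.end, name=f"{r.region_id}|{r.context}|{r.status}")
            for r in sig.itertuples()
        ],
        out / "dm_promoters.bed",
    )
    _record(manifest, out, "dm", ["dm_promoters.tsv", "dm_promoters.bed"], prm)

    # ---- de -----------------------------------------------------------
    log.info("stage de: gene differential expression")
    prm = config["de"]
    cm = read_count_matrix(out / "gene_counts.tsv")
    groups = ["WT" if s.startswith("WT") else "mut" for s in cm.sample_ids]
    cm_f = cpm_filter(cm, prm["min_cpm"], groups=groups)
    de_res = nb_test(cm_f, groups, fdr=prm["fdr"], shrink=prm["shrink"])
    results_to_frame(de_res).to_csv(out / "de_genes.tsv", sep="\t", index=False)
    _record(manifest, out, "de", ["de_genes.tsv"], prm)

    # ---- clusters -----------------------------------------------------
    log.info("stage clusters: sRNA cluster calling + DE + methylation")
    prm = config["clusters"]
    reads_r = {}
    for n in sorted(reads):
        ivs = read_bed(out / f"srna_reads_{n}.bed")
        reads_r[n] = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in ivs],
                "start": [iv.start for iv in ivs],
                "end": [iv.end for iv in ivs],
                "length": [int(iv.name) for iv in ivs],
            }
        )
    clusters = call_clusters(
        reads_r, min_len=prm["min_len"], max_len=prm["max_len"],
        pad=prm["pad"], min_reads=prm["min_reads"],
    )
    categorize_clusters(clusters, ann_r, promoters)
    clusters_to_frame(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
    write_bed(
        [c.interval for c in clusters], out / "clusters.bed",
    )
    ccm = clusters_to_count_matrix(clusters)
    cgroups = ["WT" if s.startswith("WT") else "mut" for s in ccm.sample_ids]
    ccm_f = cpm_filter(ccm, prm["min_cpm"], groups=cgroups)
    cde = nb_test(ccm_f, cgroups, fdr=prm["fdr"])
    results_to_frame(cde).to_csv(out / "cluster_de.tsv", sep="\t", index=False)
    kept = {r.feature_id for r in cde}
    cdm = sctgr_methylation(
        [c for c in clusters if c.cluster_id in kept],
        sites[sample_a], sites[sample_b],
        min_coverage=config["dm"]["min_coverage"], min_dmc=config["dm"]["min_dmc"],
    )
    cdm.to_csv(out / "cluster_dm.tsv", sep="\t", index=False)
    _record(manifest, out, "clusters",
            ["clusters.tsv", "clusters.bed", "cluster_de.tsv", "cluster_dm.tsv"], prm)

    # ---- motif-enrich -------------------------------------------------
    log.info("stage motif-enrich: PWM scan + positional enrichment")
    prm = config["motif"]
    pfms = read_jaspar_pfm(out / "motif.pfm")
    genome = read_fasta(out / "genome.fa")
    regions = upstream_regions(genes, chrom_lengths, prm["window"])
    de_frame = results_to_frame(de_res)
    up_set = de_frame.loc[de_frame["status"] == "up", "feature_id"].tolist()
    set_label = "up_degs"
    if len(up_set) < 10:  # small demo runs: fall back to all significant DEGs
        up_set = de_frame.loc[de_frame["status"] != "ns", "feature_id"].tolist()
        set_label = "all_degs"
    all_gene_ids = [g.gene_id for g in genes]
    positions = np.arange(0, prm["window"] + 1, prm["step"])
    hits_all = []
    enr_rows = {}
    for pfm in pfms:
        pwm = PWM.from_pfm(pfm)
        hits = pwm_scan(genome, regions, pwm, prm["p_threshold"])
        hits_all.extend(hits)
        if len(up_set) >= 10:
            res = enrichment_test(
                hits, up_set, all_gene_ids, n_perm=prm["n_perm"],
                seed=config["seed"], positions=positions,
                motif_class=pfm.motif_id, reduction=prm["reduction"],
            )
            enr_rows[pfm.motif_id] = {
                "summary_es": res.summary_es, "z": res.z,
                "p_perm": res.p_perm, "n_perm": res.n_perm,
                "gene_set": set_label, "n_set": len(up_set),
            }
            pd.DataFrame(
                {
                    "position": res.positions,
                    "frac_set": res.frac_set,
                    "frac_all": res.frac_all,
                    "es": res.es,
                }
            ).to_csv(out / f"motif_curves_{pfm.motif_id}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(h.gene_id, h.distance, h.strand_of_hit, h.score, h.p) for h in hits_all],
        columns=["gene_id", "distance", "strand", "score", "p"],
    ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    with open(out / "motif_enrichment.json", "w") as fh:
        json.dump(enr_rows, fh, indent=2, sort_keys=True)
    _record(manifest, out, "motif",
            ["motif_hits.tsv", "motif_enrichment.json"]
            + [f"motif_curves_{p.motif_id}.tsv" for p in pfms if p.motif_id in enr_rows],
            prm)

    # ---- integrate ----------------------------------------------------
    log.info("stage integrate: cross-omics summaries")
    prm = config["integrate"]
    dm_calls = _frame_to_calls(dm_df)
    summary, per_gene = overlap_deg_dmp(de_res, dm_calls)
    per_gene.to_csv(out / "integration_per_gene.tsv", sep="\t", index=False)
    assoc = srna_methylation_association(cde, cdm, min_diff=prm["min_diff"])
    wmw = gb_vs_promoter_srna(de_res, clusters, cde)
    wmw.to_csv(out / "integration_srna_strata.tsv", sep="\t", index=False)
    integ = {
        "deg_dmp_overlap": {
            "n_deg": summary.n_deg, "n_dmp": summary.n_dmp, "n_both": summary.n_both,
            "pct_deg_with_dmp": summary.pct_deg_with_dmp,
            "pct_dmp_that_are_deg": summary.pct_dmp_that_are_deg,
        },
        "srna_methylation_association": {
            "table": assoc.table.tolist(),
            "odds_ratio": None if np.isnan(assoc.odds_ratio) else assoc.odds_ratio,
            "p": assoc.p,
        },
    }
    with open(out / "integration_summary.json", "w") as fh:
        json.dump(integ, fh, indent=2, sort_keys=True)
    _record(manifest, out, "integrate",
            ["integration_per_gene.tsv", "integration_srna_strata.tsv",
             "integration_summary.json"], prm)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _record(manifest, out, stage, files, params=None):
    manifest["stages"][stage] = {
        "params": params or {},
        "outputs": {f: _sha256(out / f) for f in sorted(files)},
    }


def _frame_to_calls(dm_df):
    calls = []
    for r in dm_df.itertuples():
        calls.append(
            DMCall(
                region=GenomicInterval(r.chrom, r.start, r.end, name=r.region_id),
                region_id=r.region_id, context=r.context,
                meth_level_a=r.meth_level_a, meth_level_b=r.meth_level_b,
                diff=r.diff, n_covered_c=r.n_covered_c, n_dmc=r.n_dmc,
                p=r.p, q=r.q, status=r.status,
            )
        )
    return calls


def output_checksums(outdir):
    """SHA-256 of every stage output (manifest itself excluded)."""
    out = Path(outdir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    sums = {}
    for stage in manifest["stages"].values():
        sums.update(stage["outputs"])
    return sums
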