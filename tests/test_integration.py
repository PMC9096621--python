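import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from photoepi.core import GenomicInterval
from photoepi.diffcounts import DifferentialResult
from photoepi.integration import (
    _wmw,
    category_distribution,
    gb_vs_promoter_srna,
    overlap_deg_dmp,
    srna_methylation_association,
)
from photoepi.methylome import DMCall
from photoepi.srna import SRNACluster


def _deg(fid, status="up", lfc=1.0):
    return DifferentialResult(fid, lfc if status != "down" else -abs(lfc),
                              50.0, 0.01, 0.01, status)


def _dmcall(gene, status="hyper", diff=0.2, context="CG"):
    return DMCall(
        region=GenomicInterval("chr1", 0, 2000, name=gene),
        region_id=gene, context=context, meth_level_a=0.5,
        meth_level_b=0.5 + diff, diff=diff, n_covered_c=50, n_dmc=15,
        p=0.001, q=0.004, status=status,
    )


class TestOverlap:
    def test_percentage_arithmetic(self):
        degs = [_deg(f"g{i}") for i in range(10)] + [
            _deg(f"x{i}", status="ns") for i in range(5)
        ]
        dmps = [_dmcall(f"g{i}") for i in range(4)] + [
            _dmcall(f"y{i}") for i in range(6)
        ] + [_dmcall("g9", status="ns")]
        summary, frame = overlap_deg_dmp(degs, dmps)
        assert (summary.n_deg, summary.n_dmp, summary.n_both) == (10, 10, 4)
        assert summary.pct_deg_with_dmp == pytest.approx(40.0)
        assert summary.pct_dmp_that_are_deg == pytest.approx(40.0)
        assert "promoter_diff_CG" in frame.columns

    def test_disjoint_sets(self):
        degs = [_deg("a"), _deg("b")]
        dmps = [_dmcall("a", status="ns"), _dmcall("b", status="ns")]
        summary, _ = overlap_deg_dmp(degs, dmps)
        assert summary.n_both == 0

    def test_no_shared_universe_rejected(self):
        with pytest.raises(ValueError, match="no shared"):
            overlap_deg_dmp([_deg("a")], [_dmcall("zzz")])


def _cluster_dm_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["region_id", "context", "diff", "n_covered_c", "status"],
    )


class TestAssociation:
    def test_fisher_p_matches_enumeration(self):
        # force the 2x2 [[30,10],[10,50]] through the association path
        de = []
        rows = []
        i = 0
        for acc, met, n in ((True, True, 30), (True, False, 10),
                            (False, True, 10), (False, False, 50)):
            for _ in range(n):
                cid = f"c{i}"; i += 1
                de.append(_deg(cid, status="up" if acc else "ns"))
                rows.append((cid, "CG", 0.2 if met else 0.0, 20,
                             "hyper" if met else "ns"))
        table = srna_methylation_association(de, _cluster_dm_frame(rows))
        # independent oracle: scipy on the explicit table
        from scipy.stats import fisher_exact
        assert table.table.tolist() == [[30, 10], [10, 50]]
        assert table.p == pytest.approx(fisher_exact([[30, 10], [10, 50]])[1], rel=1e-9)
        assert table.odds_ratio == pytest.approx((30 * 50) / (10 * 10))

    def test_five_percent_floor_excludes_small_differences(self):
        de = [_deg("c0", "up"), _deg("c1", "ns"), _deg("c2", "up"), _deg("c3", "ns")]
        rows = [("c0", "CG", 0.04, 20, "hyper"),  # significant but < 5%
                ("c1", "CG", 0.20, 20, "hyper"),
                ("c2", "CG", 0.30, 20, "hyper"),
                ("c3", "CG", 0.00, 20, "ns")]
        table = srna_methylation_association(de, _cluster_dm_frame(rows))
        assert table.table.tolist() == [[1, 1], [1, 1]]

    def test_degenerate_margin_warns_p_one(self):
        de = [_deg("c0", "ns"), _deg("c1", "ns")]
        rows = [("c0", "CG", 0.0, 10, "ns"), ("c1", "CG", 0.0, 10, "ns")]
        with pytest.warns(UserWarning, match="zero margin"):
            table = srna_methylation_association(de, _cluster_dm_frame(rows))
        assert table.p == 1.0

    def test_axis_swap_symmetry(self):
        """Fisher's p is invariant under transposing the 2x2 table."""
        from photoepi.stats import fisher_exact_table

        _, p1 = fisher_exact_table([[12, 3], [7, 30]])
        _, p2 = fisher_exact_table([[12, 7], [3, 30]])
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestWilcoxon:
    def test_exact_small_sample_example(self):
        u, p, method = _wmw([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p, _ = _wmw([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_close_to_asymptotic_at_n20(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.4, 1, 20)
        p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        p_asym = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01

    def test_strata_and_skipping(self):
        degs = [_deg("g1", "up"), _deg("g2", "down")]
        clusters = []
        cde = []
        for i in range(6):
            c = SRNACluster(f"c{i}", GenomicInterval("chr1", i * 100, i * 100 + 50))
            c.category = "gene_body" if i % 2 else "promoter"
            c.linked_gene = "g1"
            clusters.append(c)
            cde.append(_deg(f"c{i}", "up", lfc=float(i)))
        out = gb_vs_promoter_srna(degs, clusters, cde)
        up = out[out["contrast"] == "up:P_vs_GB"].iloc[0]
        assert up["n_a"] == 3 and up["n_b"] == 3 and up["method"] == "exact"
        down = out[out["contrast"] == "down:P_vs_GB"].iloc[0]
        assert down["method"] == "skipped"


class TestCategoryDistribution:
    def test_fraction_arithmetic(self):
        genes = [f"g{i}" for i in range(100)]
        cmap = {g: ("X" if i < 50 else "Y") for i, g in enumerate(genes)}
        out = category_distribution(genes, cmap)
        assert out.set_index("category").loc["X", "fraction"] == pytest.approx(0.5)

    def test_rare_category_collapsed_into_other(self):
        genes = [f"g{i}" for i in range(100)]
        cmap = {g: "common" for g in genes[:-1]}
        cmap[genes[-1]] = "rare"  # 1% < 2% display floor
        out = category_distribution(genes, cmap)
        assert "rare" not in set(out["category"])
        assert "other" in set(out["category"])

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(200)]
        cmap = {g: f"cat{rng.integers(8)}" for g in genes}
        out = category_distribution(genes, cmap)
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_label_split_preserved(self):
        genes = ["a", "b", "c", "d"]
        cmap = {g: "X" for g in genes}
        labels = {"a": "up", "b": "up", "c": "down", "d": "down"}
        out = category_distribution(genes, cmap, labels=labels)
        row = out.set_index("category").loc["X"]
        assert row["n_up"] == 2 and row["n_down"] == 2

    def test_low_coverage_warns(self):
        with pytest.warns(UserWarning, match="covers only"):
            category_distribution(["a", "b", "c"], {"a": "X"})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            category_distribution([], {})


class TestCoupledScenarios:
    """Cross-omics recovery when effects are planted jointly across layers."""

    @pytest.fixture(scope="class")
    def study(self):
        from photoepi.synthetic import SimulationConfig, simulate_genome

        cfg = SimulationConfig(seed=31, n_chroms=2, chrom_len=250_000,
                               n_genes=80, n_tes=30)
        seqs, ann = simulate_genome(cfg)
        return cfg, seqs, ann

    def test_dmrs_planted_on_deg_promoters_raise_overlap(self, study):
        """When methylation changes are planted on DEG promoters, far more
        DEGs carry DMPs than the genome-wide DMP fraction predicts."""
        from photoepi.diffcounts import nb_test
        from photoepi.methylome import call_region_dm, promoter_regions
        from photoepi.synthetic import simulate_counts, simulate_methylomes

        cfg, seqs, ann = study
        genes = [m for m in ann if m.feature_class == "gene"]
        rng = np.random.default_rng(1)
        deg_genes = rng.choice([g.gene_id for g in genes], 16, replace=False)
        planted = {g: (2.0 if i % 2 else -2.0) for i, g in enumerate(deg_genes)}
        counts, _ = simulate_counts(ann, cfg, planted=planted)
        de = nb_test(counts, ["WT"] * 3 + ["mut"] * 3)
        reports, _ = simulate_methylomes(seqs, ann, cfg, dmr_gene_ids=deg_genes)
        promoters = promoter_regions(genes, 2000, {c: len(s) for c, s in seqs.items()})
        dm = call_region_dm(reports["WT"], reports["mut"], promoters, cfg.dmr_context)
        from photoepi.integration import overlap_deg_dmp

        summary, _ = overlap_deg_dmp(de, dm)
        null_fraction = 100.0 * summary.n_dmp / len(genes)
        assert summary.pct_deg_with_dmp > max(50.0, 2 * null_fraction)

    def test_coupled_srna_methylation_association_is_detected(self, study):
        """sRNA loci planted inside planted DMRs make the accumulation x
        methylation 2x2 association strongly significant."""
        from photoepi.core import GenomicInterval
        from photoepi.diffcounts import cpm_filter, nb_test
        from photoepi.srna import call_clusters, clusters_to_count_matrix, sctgr_methylation
        from photoepi.synthetic import simulate_methylomes, simulate_srna_reads
        from photoepi.integration import srna_methylation_association

        cfg, seqs, ann = study
        reports, mtruth = simulate_methylomes(seqs, ann, cfg)
        coupled = []
        for i, (iv, _ctx, delta) in enumerate(mtruth.dmr_regions):
            mid = (iv.start + iv.end) // 2
            coupled.append(
                (GenomicInterval(iv.chrom, mid - 150, mid + 150, name=f"cpl{i}"),
                 2.0 if delta > 0 else -2.0)
            )
        reads, _ = simulate_srna_reads(seqs, ann, cfg, coupled_loci=coupled)
        clusters = call_clusters(reads)
        groups = ["WT"] * 3 + ["mut"] * 3
        cm = cpm_filter(clusters_to_count_matrix(clusters), 2, groups=groups)
        cde = nb_test(cm, groups)
        kept = {r.feature_id for r in cde}
        cdm = sctgr_methylation(
            [c for c in clusters if c.cluster_id in kept],
            reports["WT"], reports["mut"], contexts=(cfg.dmr_context,),
        )
        assoc = srna_methylation_association(cde, cdm)
        assert assoc.p < 0.005
        assert assoc.odds_ratio > 1

    def test_gene_body_coupling_shifts_gb_stratum_only(self, study):
        """sRNA changes coupled to expression in gene bodies (RdDM-like)
        separate up- from down-DEGs in the GB stratum but not in promoters."""
        from photoepi.core import GenomicInterval
        from photoepi.diffcounts import cpm_filter, nb_test
        from photoepi.methylome import promoter_regions
        from photoepi.srna import call_clusters, categorize_clusters, clusters_to_count_matrix
        from photoepi.synthetic import simulate_counts, simulate_srna_reads
        from photoepi.integration import gb_vs_promoter_srna

        cfg, seqs, ann = study
        genes = [m for m in ann if m.feature_class == "gene"]
        rng = np.random.default_rng(2)
        chosen = rng.choice(len(genes), 30, replace=False)
        planted, coupled = {}, []
        for j, gi in enumerate(chosen):
            g = genes[gi]
            sign = 1.0 if j % 2 else -1.0
            planted[g.gene_id] = sign * 2.0
            body = g.interval
            mid = (body.start + body.end) // 2
            coupled.append((GenomicInterval(body.chrom, mid - 100, mid + 100), sign * 1.5))
            prom_start = body.start - 1500 if body.strand == "+" else body.end + 1300
            coupled.append((GenomicInterval(body.chrom, prom_start, prom_start + 200), 0.0))
        counts, _ = simulate_counts(ann, cfg, planted=planted)
        groups = ["WT"] * 3 + ["mut"] * 3
        de = nb_test(counts, groups)
        reads, _ = simulate_srna_reads(seqs, ann, cfg, coupled_loci=coupled)
        clusters = call_clusters(reads)
        promoters = promoter_regions(genes, 2000, {c: len(s) for c, s in seqs.items()})
        categorize_clusters(clusters, ann, promoters)
        cm = cpm_filter(clusters_to_count_matrix(clusters), 2, groups=groups)
        cde = nb_test(cm, groups)
        out = gb_vs_promoter_srna(de, clusters, cde).set_index("contrast")
        assert out.loc["GB:up_vs_down", "p"] < 0.01
        assert out.loc["P:up_vs_down", "p"] > 0.05
        assert out.loc["GB:up_vs_down", "median_a"] > out.loc["GB:up_vs_down", "median_b"]
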