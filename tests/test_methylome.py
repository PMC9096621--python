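import itertools
import math

import numpy as np
import pandas as pd
import pytest

from photoepi.core import CytosineSite, GeneModel, GenomicInterval
from photoepi.methylome import (
    assign_context,
    bin_profile,
    call_region_dm,
    cytosine_catalogue,
    promoter_regions,
)
from photoepi.methylome import test_cytosine as cytosine_fisher_test


class TestAssignContext:
    def test_basic_examples(self):
        assert assign_context({"c": "ACGTA"}, "c", 1, "+") == "CG"
        assert assign_context({"c": "ACAGT"}, "c", 1, "+") == "CHG"
        assert assign_context({"c": "ACAAT"}, "c", 1, "+") == "CHH"

    def test_minus_strand_uses_reverse_complement(self):
        # G at pos 2 of "ACG" is a C on the - strand; upstream C makes it CG
        assert assign_context({"c": "ACG"}, "c", 2, "-") == "CG"
        assert assign_context({"c": "CAG"}, "c", 2, "-") == "CHG"
        assert assign_context({"c": "AAG"}, "c", 2, "-") == "CHH"

    def test_chromosome_end_defaults_to_chh(self):
        assert assign_context({"c": "AC"}, "c", 1, "+") == "CHH"

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError):
            assign_context({"c": "AAAA"}, "c", 1, "+")

    def test_exhaustive_trinucleotide_table(self):
        """All C-initial trinucleotides partition 4 CG / 3 CHG / 9 CHH per
        downstream dinucleotide (16/12/36 when scaled over all 64 patterns),
        identically on both strands."""
        tallies = {"CG": 0, "CHG": 0, "CHH": 0}
        comp = str.maketrans("ACGT", "TGCA")
        for b1, b2 in itertools.product("ACGT", repeat=2):
            tri = "C" + b1 + b2
            ctx = assign_context({"c": tri}, "c", 0, "+")
            # independent rule: CG iff b1 == G, CHG iff b2 == G
            expected = "CG" if b1 == "G" else ("CHG" if b2 == "G" else "CHH")
            assert ctx == expected
            rc = tri.translate(comp)[::-1]
            assert assign_context({"c": rc}, "c", 2, "-") == ctx
            tallies[ctx] += 1
        assert tallies == {"CG": 4, "CHG": 3, "CHH": 9}

    def test_catalogue_agrees_with_single_site_rule(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 300))
        cat = cytosine_catalogue(seq)
        for row in cat.sample(n=40, random_state=1).itertuples():
            assert assign_context({"c": seq}, "c", row.pos, row.strand) == row.context


class TestCytosineTest:
    def test_extreme_table_matches_hypergeometric(self):
        a = CytosineSite("c", 0, "+", "CG", 10, 10)
        b = CytosineSite("c", 0, "+", "CG", 0, 10)
        p, diff = cytosine_fisher_test(a, b)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert diff == -1.0

    def test_identical_proportions(self):
        a = CytosineSite("c", 0, "+", "CG", 5, 10)
        p, diff = cytosine_fisher_test(a, a)
        assert p == 1.0 and diff == 0.0


class TestPromoters:
    def _gene(self, start, end, strand, gid="g"):
        return GeneModel(gid, GenomicInterval("chr1", start, end, strand), "gene")

    def test_plus_strand_upstream(self):
        (iv,) = promoter_regions([self._gene(5000, 8000, "+")])
        assert (iv.start, iv.end) == (3000, 5000)

    def test_minus_strand_upstream(self):
        (iv,) = promoter_regions([self._gene(5000, 8000, "-")], chrom_lengths={"chr1": 10_000})
        assert (iv.start, iv.end) == (8000, 10_000)

    def test_clipped_at_chromosome_start(self):
        (iv,) = promoter_regions([self._gene(500, 900, "+")])
        assert (iv.start, iv.end) == (0, 500)

    def test_zero_length_promoter_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty promoter"):
            out = promoter_regions([self._gene(0, 900, "+")])
        assert out == []


def _frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "total"])


class TestRegionCalling:
    def _paired_frames(self, n_sites, meth_a, meth_b, total=20, start=100):
        rows_a, rows_b = [], []
        for i in range(n_sites):
            rows_a.append(("chr1", start + i * 3, "+", "CG", meth_a, total))
            rows_b.append(("chr1", start + i * 3, "+", "CG", meth_b, total))
        return _frame(rows_a), _frame(rows_b)

    def test_region_with_enough_dmcs_called_with_sign(self):
        a, b = self._paired_frames(12, meth_a=2, meth_b=18)
        region = GenomicInterval("chr1", 0, 1000, name="r1")
        (call,) = call_region_dm(a, b, [region], "CG")
        assert call.n_dmc >= 10 and call.status == "hyper" and call.diff > 0

    def test_min_dmc_rule_blocks_call_despite_significance(self):
        """Nine DMCs are not enough even at a tiny region q-value."""
        a, b = self._paired_frames(9, meth_a=2, meth_b=18)
        region = GenomicInterval("chr1", 0, 1000, name="r1")
        (call,) = call_region_dm(a, b, [region], "CG")
        assert call.q < 0.05 and call.n_dmc == 9 and call.status == "ns"

    def test_uncovered_region_flagged_ns(self):
        a, b = self._paired_frames(5, 2, 18)
        regions = [
            GenomicInterval("chr1", 0, 1000, name="r1"),
            GenomicInterval("chr2", 0, 1000, name="empty"),
        ]
        calls = call_region_dm(a, b, regions, "CG")
        empty = calls[1]
        assert empty.n_covered_c == 0 and empty.status == "ns" and np.isnan(empty.p)

    def test_coverage_filter_excludes_thin_sites(self):
        a = _frame([("chr1", 5, "+", "CG", 2, 9), ("chr1", 8, "+", "CG", 2, 20)])
        b = _frame([("chr1", 5, "+", "CG", 9, 9), ("chr1", 8, "+", "CG", 18, 20)])
        (call,) = call_region_dm(a, b, [GenomicInterval("chr1", 0, 100, name="r")], "CG")
        assert call.n_covered_c == 1  # the 9x site is below 10x

    def test_group_swap_flips_status_and_negates_diff(self, small_study):
        reports = small_study["reports"]
        promoters = small_study["promoters"]
        fwd = call_region_dm(reports["WT"], reports["mut"], promoters, "CHH", min_dmc=5)
        rev = call_region_dm(reports["mut"], reports["WT"], promoters, "CHH", min_dmc=5)
        flip = {"hyper": "hypo", "hypo": "hyper", "ns": "ns"}
        for f, r in zip(fwd, rev):
            assert r.status == flip[f.status]
            if not np.isnan(f.diff):
                assert r.diff == pytest.approx(-f.diff, abs=1e-12)
                assert r.p == pytest.approx(f.p, rel=1e-9)

    def test_planted_dmrs_recovered_with_correct_sign(self, small_study):
        reports = small_study["reports"]
        truth = small_study["truth"]
        cfg = small_study["cfg"]
        calls = call_region_dm(
            reports["WT"], reports["mut"], small_study["promoters"], cfg.dmr_context
        )
        by_id = {c.region_id: c for c in calls}
        for iv, _ctx, delta in truth.dmr_regions:
            call = by_id[iv.name]
            assert call.status == ("hyper" if delta > 0 else "hypo")


class TestBinProfile:
    def test_bins_tile_and_short_last_bin(self, site_frame):
        sites = {
            "WT": site_frame([("chr1", 10, "+", "CG", 8, 10)]),
            "mut": site_frame([("chr1", 10, "+", "CG", 1, 10)]),
        }
        df = bin_profile(sites, {"chr1": 2_500_000}, [], "WT", bin_size=1_000_000)
        starts = sorted(df["bin_start"].unique())
        assert starts == [0, 1_000_000, 2_000_000]
        last = df[df["bin_start"] == 2_000_000].iloc[0]
        assert last["bin_size"] == 500_000

    def test_difference_classification(self, site_frame):
        sites = {
            "WT": site_frame([("chr1", 10, "+", "CG", 50, 100)]),
            "mut": site_frame([("chr1", 10, "+", "CG", 43, 100)]),
        }
        df = bin_profile(sites, {"chr1": 1_000_000}, [], "WT")
        row = df[(df["sample"] == "mut") & (df["context"] == "CG") & (df["n_sites"] > 0)].iloc[0]
        assert row["diff_vs_ref"] == pytest.approx(-0.07)
        assert row["status"] == "hypo"

    def test_empty_bin_is_nan_not_zero(self, site_frame):
        sites = {"WT": site_frame([]), "mut": site_frame([])}
        df = bin_profile(sites, {"chr1": 1_000_000}, [], "WT")
        assert df["meth_level"].isna().all()

    def test_te_covering_full_bin_density(self, site_frame):
        te = GeneModel(
            "te1", GenomicInterval("chr1", 0, 1_000_000, "."), "TE"
        )
        sites = {"WT": site_frame([("chr1", 10, "+", "CG", 5, 10)]),
                 "mut": site_frame([("chr1", 10, "+", "CG", 5, 10)])}
        df = bin_profile(sites, {"chr1": 1_000_000}, [te], "WT")
        assert (df["density_tes"] == 1e6).all()

    def test_common_coverage_restriction(self, site_frame):
        # site covered 10x in WT but only 5x in mut must not contribute
        sites = {
            "WT": site_frame([("chr1", 10, "+", "CG", 8, 10)]),
            "mut": site_frame([("chr1", 10, "+", "CG", 2, 5)]),
        }
        df = bin_profile(sites, {"chr1": 1_000_000}, [], "WT")
        assert (df["n_sites"] == 0).all()
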