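import itertools

import numpy as np
import pytest

from photoepi.core import PFM, GeneModel, GenomicInterval
from photoepi.motifs import (
    PWM,
    cumulative_fraction,
    enrichment_test,
    min_hit_distance,
    MotifHit,
    pwm_scan,
    upstream_regions,
)
from photoepi.synthetic import (
    SimulationConfig,
    make_demo_pfm,
    simulate_genome,
    simulate_motif_landscape,
)

CONSENSUS = "CACGTGGGCA"
RC = CONSENSUS[::-1].translate(str.maketrans("ACGT", "TGCA"))


@pytest.fixture(scope="module")
def demo_pwm():
    return PWM.from_pfm(make_demo_pfm())


class TestPWM:
    def test_pseudocount_probabilities(self):
        pfm = PFM("m", np.array([[10, 0], [0, 10], [0, 0], [0, 0]], dtype=float))
        pwm = PWM.from_pfm(pfm)
        # p_A(col 0) = (10 + 0.25) / 11
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2((10.25 / 11) / 0.25))

    def test_uniform_pfm_has_no_significant_scores(self):
        pfm = PFM("u", np.full((4, 6), 5.0))
        pwm = PWM.from_pfm(pfm)
        with pytest.raises(ValueError, match="no score reaches"):
            pwm.threshold_for_p(1e-5)

    def test_score_distribution_sums_to_one(self, demo_pwm):
        _, probs = demo_pwm.score_distribution()
        assert probs.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("L", [2, 3, 5])
    def test_dp_tail_equals_exhaustive_enumeration(self, L):
        rng = np.random.default_rng(L)
        pwm = PWM.from_pfm(PFM("r", rng.integers(0, 30, (4, L)) + 1.0))
        scores, probs = pwm.score_distribution()
        tail = np.cumsum(probs[::-1])[::-1]
        q = pwm.quantized
        exhaustive = [
            sum(q[b, j] for j, b in enumerate(combo))
            for combo in itertools.product(range(4), repeat=L)
        ]
        exhaustive = np.array(exhaustive)
        for idx in range(0, len(scores), max(1, len(scores) // 50)):
            assert tail[idx] == pytest.approx(
                (exhaustive >= scores[idx]).mean(), abs=1e-12
            )


class TestScanning:
    def _planted_setup(self, strand, distance=500):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 80_000, p=[0.32, 0.18, 0.18, 0.32]))
        if strand == "+":
            gene = GeneModel("g", GenomicInterval("chr1", 25_000, 28_000, "+"), "gene")
            a = gene.interval.start - distance - len(CONSENSUS)
        else:
            gene = GeneModel("g", GenomicInterval("chr1", 5_000, 8_000, "-"), "gene")
            a = gene.interval.end + distance
        planted = CONSENSUS if strand == "+" else RC
        seqs = {"chr1": seq[:a] + planted + seq[a + len(planted):]}
        return seqs, gene

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_consensus_found_at_distance(self, demo_pwm, strand):
        seqs, gene = self._planted_setup(strand)
        regions = upstream_regions([gene], {c: len(s) for c, s in seqs.items()})
        hits = pwm_scan(seqs, regions, demo_pwm, 1e-5)
        assert any(h.distance == 500 and h.gene_id == gene.gene_id for h in hits)

    def test_region_shorter_than_motif_yields_no_hits(self, demo_pwm):
        gene = GeneModel("g", GenomicInterval("c", 4, 100, "+"), "gene")
        regions = upstream_regions([gene], {"c": 100}, window=20_000)
        hits = pwm_scan({"c": "ACGT" * 25}, regions, demo_pwm, 1e-5)
        assert hits == []

    def test_reverse_complement_mirror_invariance(self, demo_pwm):
        """Mirroring the genome (reverse complement + flipped annotation)
        leaves every hit distance unchanged."""
        seqs, gene = self._planted_setup("+")
        chrom = gene.interval.chrom
        L = len(seqs[chrom])
        comp = str.maketrans("ACGT", "TGCA")
        mirrored = {chrom: seqs[chrom].translate(comp)[::-1]}
        flip = {"+": "-", "-": "+"}
        m_iv = GenomicInterval(
            chrom, L - gene.interval.end, L - gene.interval.start,
            flip[gene.interval.strand],
        )
        m_gene = GeneModel(gene.gene_id, m_iv, "gene")
        h1 = pwm_scan(seqs, upstream_regions([gene], {chrom: L}), demo_pwm, 1e-5)
        h2 = pwm_scan(mirrored, upstream_regions([m_gene], {chrom: L}), demo_pwm, 1e-5)
        assert sorted((h.gene_id, h.distance, h.score) for h in h1) == sorted(
            (h.gene_id, h.distance, h.score) for h in h2
        )


class TestCurves:
    def test_step_function_for_common_hit_distance(self):
        genes = [f"g{i}" for i in range(5)]
        hits = [MotifHit(g, 500, "+", 1.0, 1e-6) for g in genes]
        pos = np.arange(0, 2001, 100)
        f = cumulative_fraction(hits, genes, pos)
        assert (f[pos < 500] == 0).all() and (f[pos >= 500] == 1).all()

    def test_no_hits_gives_zero_curve(self):
        f = cumulative_fraction([], ["g1", "g2"], np.arange(0, 1001, 100))
        assert (f == 0).all()

    def test_matches_min_distance_oracle_on_random_fixture(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        hits = [
            MotifHit(genes[rng.integers(40)], int(rng.integers(0, 20_000)), "+", 0.0, 1e-6)
            for _ in range(200)
        ]
        pos = np.arange(0, 20_001, 100)
        f = cumulative_fraction(hits, genes, pos)
        # brute-force per-gene minimum recomputation
        for x in pos[::20]:
            manual = np.mean([
                any(h.distance <= x for h in hits if h.gene_id == g) for g in genes
            ])
            assert f[list(pos).index(x)] == pytest.approx(manual)

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        hits = [
            MotifHit(genes[rng.integers(30)], int(rng.integers(0, 20_000)), "+", 0.0, 1e-6)
            for _ in range(100)
        ]
        f = cumulative_fraction(hits, genes)
        assert (np.diff(f) >= 0).all()

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cumulative_fraction([], [])


@pytest.fixture(scope="module")
def landscape():
    cfg = SimulationConfig(seed=5)
    _, ann = simulate_genome(cfg)
    hits, truth = simulate_motif_landscape(ann, cfg)
    gene_ids = [m.gene_id for m in ann if m.feature_class == "gene"]
    return hits, truth, gene_ids, ann


class TestEnrichment:

    def test_set_equal_to_all_genes_gives_zero_es(self, landscape):
        hits, _, gene_ids, _ = landscape
        res = enrichment_test(hits, gene_ids, gene_ids, n_perm=200, seed=0)
        assert (res.es == 0).all() and res.summary_es == 0.0

    def test_planted_enrichment_detected(self, landscape):
        hits, truth, gene_ids, _ = landscape
        res = enrichment_test(hits, truth.enriched_gene_set[:100], gene_ids,
                              n_perm=1000, seed=1)
        assert res.p_perm <= 0.001 and res.z > 3

    def test_p_perm_bounds_and_determinism(self, landscape):
        hits, truth, gene_ids, _ = landscape
        a = enrichment_test(hits, truth.enriched_gene_set[:50], gene_ids, n_perm=99, seed=4)
        b = enrichment_test(hits, truth.enriched_gene_set[:50], gene_ids, n_perm=99, seed=4)
        assert a.p_perm == b.p_perm and a.z == b.z
        assert 1 / 100 <= a.p_perm <= 1.0

    def test_extra_sites_land_inside_window(self, landscape):
        """With p_extra=1 every enriched gene has a hit within the planted
        TSS window."""
        cfg = SimulationConfig(seed=6, motif_p_extra=1.0)
        _, ann = simulate_genome(cfg)
        hits, truth = simulate_motif_landscape(ann, cfg)
        d = min_hit_distance(hits, truth.enriched_gene_set)
        assert (d < cfg.motif_tss_window).all()

    def test_small_regulated_set_rejected(self, landscape):
        hits, _, gene_ids, _ = landscape
        with pytest.raises(ValueError, match="at least 10"):
            enrichment_test(hits, gene_ids[:5], gene_ids, n_perm=10, seed=0)

    def test_set_not_subset_rejected(self, landscape):
        hits, _, gene_ids, _ = landscape
        with pytest.raises(ValueError, match="subset"):
            enrichment_test(hits, ["nope"] * 10, gene_ids, n_perm=10, seed=0)
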