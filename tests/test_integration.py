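import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cageqtl import integration
from cageqtl.io import GenomicInterval, GenotypeMatrix
from cageqtl.synthetic import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="module")
def genotypes():
    cfg = SimulationConfig(n_samples=120, n_variants=400, ld_block_span=4000,
                           n_genes=10, n_enhancers=4, tad_span=150_000,
                           maf_range=(0.2, 0.5), seed=33)
    return simulate_genotypes(cfg)


class TestPi1:
    def test_uniform_null_near_zero(self, rng):
        res = integration.pi1(rng.uniform(size=5000), n_bootstrap=0)
        assert res["pi1"] <= 0.05

    def test_all_tiny_pvalues_near_one(self):
        res = integration.pi1(np.full(1000, 1e-6), n_bootstrap=0)
        assert res["pi1"] > 0.95

    def test_recovers_eighty_percent_alternatives(self, rng):
        p = np.concatenate([rng.uniform(size=1000),
                            rng.beta(0.02, 20, size=4000)])
        res = integration.pi1(p, n_bootstrap=20)
        assert abs(res["pi1"] - 0.8) <= 0.05
        assert res["pi1_se"] < 0.05


class TestLdStats:
    def test_identical_variant(self, genotypes):
        v = genotypes.variants.iloc[0]["id"]
        r2, rho = integration.ld_stats(genotypes, v, v)
        assert r2 == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        variants = pd.DataFrame({
            "id": ["a", "b"], "chrom": ["chr1"] * 2, "pos": [1, 2],
            "ref": ["A"] * 2, "alt": ["G"] * 2, "maf": [0.4, 0.4],
            "alt_count": [5, 5],
        })
        dos = np.array([[0, 0], [1, 1], [2, 1], [0, 1], [1, 2], [2, 2]],
                       dtype=float)
        gm = GenotypeMatrix([f"s{i}" for i in range(6)], variants, dos)
        r2, rho = integration.ld_stats(gm, "a", "b")
        r_expected = np.corrcoef(dos[:, 0], dos[:, 1])[0, 1]
        assert r2 == pytest.approx(r_expected ** 2)
        assert rho == pytest.approx(stats.spearmanr(dos[:, 0],
                                                    dos[:, 1]).statistic)

    def test_independent_variants_mean_r2_near_1_over_n(self, rng):
        n = 200
        g1 = rng.binomial(2, 0.4, size=(n, 300)).astype(float)
        g2 = rng.binomial(2, 0.4, size=(n, 300)).astype(float)
        r2 = [np.corrcoef(g1[:, j], g2[:, j])[0, 1] ** 2 for j in range(300)]
        assert np.mean(r2) == pytest.approx(1 / n, rel=0.4)

    def test_monomorphic_rejected(self):
        variants = pd.DataFrame({
            "id": ["a", "b"], "chrom": ["chr1"] * 2, "pos": [1, 2],
            "ref": ["A"] * 2, "alt": ["G"] * 2, "maf": [0.0, 0.4],
            "alt_count": [0, 5],
        })
        dos = np.array([[0, 0], [0, 1], [0, 2], [0, 1]], dtype=float)
        gm = GenotypeMatrix([f"s{i}" for i in range(4)], variants, dos)
        with pytest.raises(ValueError):
            integration.ld_stats(gm, "a", "b")


class TestRtc:
    def test_rank_zero_gives_one(self, genotypes, rng):
        # the GWAS variant IS the causal variant: its correction destroys the
        # association most, so it ranks 0 and RTC = (N - 0)/N = 1
        v = genotypes.variants
        qtl_col = 5
        y = 1.0 * genotypes.dosages[:, qtl_col] + rng.normal(
            size=genotypes.n_samples)
        interval = GenomicInterval("chr1", 0, int(v["pos"].max()) + 1, ".", "iv")
        res = integration.rtc(y, genotypes, v.iloc[qtl_col]["id"],
                              v.iloc[qtl_col]["id"], interval)
        assert res.rank == 0
        assert res.rtc == pytest.approx(1.0)
        assert res.high_confidence

    def test_needs_two_variants(self, genotypes, rng):
        v = genotypes.variants
        tiny = GenomicInterval("chr1", int(v.iloc[0]["pos"]),
                               int(v.iloc[0]["pos"]) + 1, ".", "iv")
        with pytest.raises(ValueError):
            integration.rtc(rng.normal(size=genotypes.n_samples), genotypes,
                            v.iloc[0]["id"], v.iloc[0]["id"], tiny)


class TestGwasEnrichment:
    def test_qtl_set_equal_to_gwas_set(self, genotypes):
        ids = list(genotypes.variants["id"].iloc[:20])
        catalog = genotypes.variants.iloc[:20][["id", "chrom", "pos"]].rename(
            columns={"id": "variant_id"})
        catalog["trait"] = "t"
        res = integration.gwas_overlap_enrichment(
            ids, catalog, genotypes,
            tss_positions=np.linspace(0, 150_000, 10), n_perm=100, seed=0)
        assert res.observed == 20
        assert res.odds_ratio > 1
        assert res.p >= 1 / 101

    def test_observed_count_matches_bruteforce(self, genotypes, rng):
        v = genotypes.variants
        qtl_ids = list(rng.choice(v["id"], size=30, replace=False))
        gwas_rows = rng.choice(v.index, size=15, replace=False)
        catalog = v.loc[gwas_rows, ["id", "chrom", "pos"]].rename(
            columns={"id": "variant_id"})
        catalog["trait"] = "t"
        flank, r2_min = 20_000, 0.5
        res = integration.gwas_overlap_enrichment(
            qtl_ids, catalog, genotypes, tss_positions=[0, 75_000],
            flank=flank, r2_min=r2_min, n_perm=50, seed=1)
        gwas_ids = set(catalog["variant_id"])
        expected = 0
        for q in qtl_ids:
            if q in gwas_ids:
                expected += 1
                continue
            qpos = int(v.loc[v["id"] == q, "pos"].iloc[0])
            hit = False
            for g in catalog.itertuples(index=False):
                if abs(g.pos - qpos) <= flank:
                    r2, _ = integration.ld_stats(genotypes, q, g.variant_id)
                    if r2 > r2_min:
                        hit = True
                        break
            expected += hit
        assert res.observed == expected

    def test_null_self_consistency(self, genotypes, rng):
        # QTL variants drawn at random behave like the matched null
        v = genotypes.variants
        qtl_ids = list(rng.choice(v["id"], size=25, replace=False))
        gwas_rows = rng.choice(v.index, size=10, replace=False)
        catalog = v.loc[gwas_rows, ["id", "chrom", "pos"]].rename(
            columns={"id": "variant_id"})
        catalog["trait"] = "t"
        res = integration.gwas_overlap_enrichment(
            qtl_ids, catalog, genotypes, tss_positions=[0, 75_000],
            flank=10_000, n_perm=200, seed=2)
        assert 0.3 < res.odds_ratio < 3.0
        assert res.p > 0.01


class TestCit:
    def test_direction_swap_is_exact_relabel(self, rng):
        g = rng.binomial(2, 0.3, size=100).astype(float)
        M = g + rng.normal(size=100)
        T = M + rng.normal(size=100)
        a = integration.cit_test(g, M, T, n_perm=50, seed=4)
        b = integration.cit_test(g, T, M, n_perm=50, seed=4)
        assert a["forward"] == b["reverse"]
        assert a["reverse"] == b["forward"]

    def test_pure_noise_outcome_component1_uniform(self, rng):
        ps = []
        for k in range(80):
            g = rng.binomial(2, 0.4, size=60).astype(float)
            M = g + rng.normal(size=60)
            T = rng.normal(size=60)
            res = integration.cit_test(g, M, T, n_perm=20, seed=k)
            ps.append(res["forward"]["p1"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self, rng):
        g = np.ones(50)
        with pytest.raises(ValueError):
            integration.cit_test(g, rng.normal(size=50), rng.normal(size=50))

    def test_chain_detected_in_causal_direction(self, rng):
        hits_fwd, hits_rev = 0, 0
        n_rep = 20
        for k in range(n_rep):
            g = rng.binomial(2, 0.3, size=150).astype(float)
            M = g + rng.normal(size=150)
            T = M + rng.normal(size=150)
            res = integration.cit_test(g, M, T, n_perm=100, seed=1000 + k)
            hits_fwd += res["forward"]["omnibus"] < 0.05
            hits_rev += res["reverse"]["omnibus"] < 0.05
        assert hits_fwd >= 0.7 * n_rep
        assert hits_rev <= 0.3 * n_rep


class TestTriplets:
    def _qtls(self, rows):
        return pd.DataFrame(rows, columns=["phenotype_id", "variant_id"])

    def test_one_enhancer_two_promoters_gives_two_triplets(self, genotypes):
        v = genotypes.variants["id"]
        eaqtls = self._qtls([("e1", v.iloc[0])])
        pairing = pd.DataFrame({"enhancer_id": ["e1", "e1"],
                                "peak_id": ["p1", "p2"]})
        puqtls = self._qtls([("p1", v.iloc[0])])
        out = integration.build_triplets(eaqtls, pairing, puqtls, genotypes)
        assert len(out) == 2
        assert out["shared_with_puqtl"].all()  # same variant is a puQTL

    def test_empty_pairing(self, genotypes):
        eaqtls = self._qtls([("e1", genotypes.variants["id"].iloc[0])])
        out = integration.build_triplets(eaqtls, pd.DataFrame(
            columns=["enhancer_id", "peak_id"]), self._qtls([]), genotypes)
        assert len(out) == 0

    def test_shared_flag_matches_bruteforce_ld(self, genotypes):
        v = genotypes.variants
        eaqtls = self._qtls([("e1", v.iloc[3]["id"])])
        pairing = pd.DataFrame({"enhancer_id": ["e1"], "peak_id": ["p1"]})
        puqtls = self._qtls([("p1", v.iloc[40]["id"]), ("p2", v.iloc[4]["id"])])
        out = integration.build_triplets(eaqtls, pairing, puqtls, genotypes,
                                         rho_min=0.8)
        best = 0.0
        for pv in (v.iloc[40]["id"], v.iloc[4]["id"]):
            _, rho = integration.ld_stats(genotypes, v.iloc[3]["id"], pv)
            best = max(best, abs(rho))
        assert bool(out.loc[0, "shared_with_puqtl"]) == (best > 0.8)


class TestAnnotateTss:
    def _annotation(self):
        transcripts = [
            GenomicInterval("chr1", 999, 1001, "+", "gA_tss",
                            {"kind": "tss", "gene_id": "gA"}),
            GenomicInterval("chr1", 1000, 1150, "+", "gA_utr_exon",
                            {"kind": "utr5_exon", "gene_id": "gA"}),
            GenomicInterval("chr1", 1150, 2000, "+", "gA_utr_intron",
                            {"kind": "utr5_intron", "gene_id": "gA"}),
            GenomicInterval("chr1", 1000, 6000, "+", "gA_body",
                            {"kind": "gene_body", "gene_id": "gA"}),
        ]
        segments = [
            GenomicInterval("chr1", 500, 6500, ".", "segP",
                            {"state": "promoter"}),
            GenomicInterval("chr1", 9000, 11_000, ".", "segE",
                            {"state": "enhancer"}),
        ]
        return transcripts, segments

    def test_upstream_500nt_same_strand(self):
        transcripts, segments = self._annotation()
        peaks = [GenomicInterval("chr1", 700, 720, "+", "up300"),
                 GenomicInterval("chr1", 400, 420, "+", "up600"),
                 GenomicInterval("chr1", 700, 720, "-", "wrong_strand")]
        out = integration.annotate_tss(peaks, transcripts, segments)
        labels = dict(zip(out["peak_id"], out["label"]))
        assert labels["up300"] == "Annotated gene"
        assert labels["up600"] != "Annotated gene"
        assert labels["wrong_strand"] != "Annotated gene"

    def test_hierarchy_on_hand_labeled_fixture(self):
        transcripts, segments = self._annotation()
        peaks = [
            ("in_utr_exon", 1100, "+", "Annotated gene"),
            ("in_utr_intron", 1500, "+", "Annotated gene"),
            ("enhancer_peak", 9500, "+", "eRNA/enhancer"),
            ("antisense", 3000, "-", "Antisense promoter"),
            ("putative_intragenic", 3000, "+", "Putative promoter"),
            ("orphan", 50_000, "+", "other"),
        ]
        ivs = [GenomicInterval("chr1", p, p + 20, s, name)
               for name, p, s, _ in peaks]
        out = integration.annotate_tss(ivs, transcripts, segments)
        labels = dict(zip(out["peak_id"], out["label"]))
        for name, _, _, expected in peaks:
            assert labels[name] == expected, name
        loc = dict(zip(out["peak_id"], out["localization"]))
        assert loc["putative_intragenic"] == "intragenic"

    def test_putative_intergenic(self):
        transcripts, segments = self._annotation()
        segments.append(GenomicInterval("chr1", 20_000, 21_000, ".", "segP2",
                                        {"state": "promoter"}))
        peaks = [GenomicInterval("chr1", 20_500, 20_520, "+", "pp")]
        out = integration.annotate_tss(peaks, transcripts, segments)
        assert out.loc[0, "label"] == "Putative promoter"
        assert out.loc[0, "localization"] == "intergenic"


class TestFeatureEnrichment:
    def test_whole_genome_annotation_gives_unit_or(self, rng):
        annotation = [GenomicInterval("chr1", 0, 10**9, ".", "all")]
        pos = rng.integers(10**5, 10**6, size=30)
        qtls = pd.DataFrame({
            "chrom": ["chr1"] * 30,
            "pos": pos,
            "anchor_pos": pos - rng.integers(0, 1000, size=30),
        })
        landscape = pd.DataFrame({"chrom": ["chr1"] * 50,
                                  "pos": rng.integers(0, 10**6, size=50)})
        res = integration.feature_enrichment(qtls, annotation, landscape,
                                             n_perm=50, seed=0)
        assert res.observed == 30
        assert res.odds_ratio == pytest.approx(1.0)

    def test_planted_enrichment_hits_p_floor(self, rng):
        # QTLs sit right on their anchors inside annotations; the landscape is
        # mostly outside them
        annotation = [GenomicInterval("chr1", k * 10_000, k * 10_000 + 100, ".",
                                      f"a{k}") for k in range(20)]
        anchor = np.array([k * 10_000 + 50 for k in range(20)])
        qtls = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": anchor,
                             "anchor_pos": anchor})
        landscape = pd.DataFrame({
            "chrom": ["chr1"] * 500,
            "pos": rng.integers(0, 200_000, size=500)})
        res = integration.feature_enrichment(qtls, annotation, landscape,
                                             n_perm=200, seed=0)
        assert res.observed == 20
        assert res.p == pytest.approx(1 / 201)
        assert res.odds_ratio > 5

    def test_observed_matches_naive_recount(self, rng):
        annotation = [GenomicInterval("chr1", int(s), int(s) + 300, ".", f"a{k}")
                      for k, s in enumerate(rng.choice(100_000, 40))]
        pos = rng.integers(0, 101_000, size=60)
        qtls = pd.DataFrame({"chrom": ["chr1"] * 60, "pos": pos,
                             "anchor_pos": pos - rng.integers(-500, 500, 60)})
        landscape = pd.DataFrame({"chrom": ["chr1"] * 100,
                                  "pos": rng.integers(0, 100_000, 100)})
        res = integration.feature_enrichment(qtls, annotation, landscape,
                                             n_perm=20, seed=0)
        naive = sum(any(iv.start <= p < iv.end for iv in annotation)
                    for p in pos)
        assert res.observed == naive

    def test_permutation_p_floor_respected(self, rng):
        annotation = [GenomicInterval("chr1", 0, 100, ".", "a")]
        qtls = pd.DataFrame({"chrom": ["chr1"], "pos": [50],
                             "anchor_pos": [50]})
        landscape = pd.DataFrame({"chrom": ["chr1"] * 10,
                                  "pos": rng.integers(10_000, 20_000, 10)})
        res = integration.feature_enrichment(qtls, annotation, landscape,
                                             n_perm=99, seed=0)
        assert res.p >= 1 / 100
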